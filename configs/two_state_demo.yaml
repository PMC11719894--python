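# Minimal two-basin demo: one condition, contact vs no-contact states.
ensemble: two_state
stride: 5
variance_threshold: 0.80
k_min: 2
k_max: 5
k_select: silhouette
n_init: 5
distance_pair: [CTD, tower]
distance_threshold: 8.0
seed: 3
frames_per_run: 100
runs_per_condition: 2
outdir: results/two_state_demo
write_trajectories: true
make_figures: true
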