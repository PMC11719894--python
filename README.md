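# mdscape

Conformational-landscape analysis of multidomain protein MD trajectories.

Large multidomain enzymes — the motivating case is a seven-domain
retrotransposon polymerase with an endonuclease (EN) domain, a tower, a
rigid fingers–palm–thumb (FPT) core, a wrist and a C-terminal domain
(CTD) — explore conformations that a single whole-protein RMSD cannot
distinguish: different domain arrangements can produce identical RMSD
values. `mdscape` implements the analysis chain that resolves them:

1. **Featurization** — every frame is described by the pairwise distances
   between a strided subset of CA atoms: with *n* feature atoms,
   *D* = *n*(*n*−1)/2 distances (a 1275-residue chain at stride 25 gives
   51 atoms and 1275 features; all CA atoms would give 812,175).
2. **Reduction** — PCA of the pooled feature matrix, keeping the smallest
   *m* with cumulative explained variance ≥ 80 %.
3. **Clustering** — full-covariance Gaussian mixtures fit by EM in the
   reduced space; the cluster count is weighed with an elbow criterion on
   the BIC-vs-K curve and a silhouette ranking; frames closest to each
   component mean are the representative structures; cluster weights and
   per-condition (apo / RNA / DNA / ternary) population tables summarize
   the landscape.
4. **Geometry** — frames are superposed on the rigid FPT core (Kabsch),
   and each domain's RMSD is computed against the initial or the iterated
   average structure *without* re-fitting (mobility relative to the core);
   `internal_rmsd` removes the domain's own rigid-body motion (internal
   flexibility). Minimum interdomain CA–CA distances classify frames as
   closed-contact (distance < 8 Å, strict) or open; side-chain salt bridges
   and hydrophobic contacts are detected for all-atom structures.

Because no reference trajectories are deposited for such systems, the
package ships a **synthetic rigid-body ensemble generator**
(`mdscape.synthetic_data`): a 213-atom seven-domain miniature whose frames
switch between a small number of planted conformational basins (rigid
per-domain transforms plus Gaussian jitter) under a Markov chain, with
per-frame ground-truth labels. Every downstream stage is validated against
that planted truth.

## Worked example

The numbered scripts under `analysis/` run the whole study: simulate both
planted ensembles, featurize + reduce, cluster, and measure domain
geometry.

```bash
python analysis/01_simulate.py
python analysis/02_featurize_reduce.py
python analysis/03_cluster.py
python analysis/04_domain_geometry.py
python analysis/05_report.py
```

The final report prints (abridged):

```
open_like:
  elbow K = 5 (silhouette best 5, second best 6)
  ARI vs planted states = 1.000; population recovery max |err| = 0.000
  CTD-tower close-contact fraction = 0.396
  mean domain RMSD (A): EN 10.1, tower 2.2, FPT 0.3, wrist 0.9, CTD 8.4
closed_like:
  elbow K = 6 (silhouette best 6, second best 5)
  ARI vs planted states = 1.000; population recovery max |err| = 0.000
  CTD-tower close-contact fraction = 0.650
  mean domain RMSD (A): EN 9.5, tower 2.1, FPT 0.3, wrist 0.8, CTD 6.1
```

Reading this: the elbow criterion recovers the planted basin counts (5
open-like, 6 closed-like); the mixture assignment reproduces the planted
state labels exactly (adjusted Rand index 1.0), so the per-condition
population tables match the planted occupancies; the fraction of frames
with minimum CTD–tower CA–CA distance below 8 Å matches each ensemble's
planted contact-state occupancy (≈ 0.40 open-like, 0.65 closed-like); and
the mean per-domain RMSD after FPT-core alignment reproduces the planted
mobility ordering EN > CTD > tower > wrist > FPT core.

The same pipeline is scriptable from a YAML config through the CLI:

```bash
mdscape run --config configs/two_state_demo.yaml
# or stage by stage: mdscape simulate / featurize / reduce / cluster / analyze
```

For real data, point `input_trajectories` at multi-model PDB files (DCD and
XTC are read through mdtraj) and supply a domain map
(`name: [start, end]`, 1-based inclusive); the default map is the
seven-domain layout EN 1–238, tower 239–439, fingers 440–557, palm
558–775, thumb 776–862, wrist 863–1061, CTD 1061–1275, with an adjusted
CTD 1068–1275 / wrist 877–1056 preset for CTD–wrist distance analyses.

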