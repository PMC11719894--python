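# Methods

## The analysis model

The package treats a set of MD runs of one multidomain protein as samples
from a small number of conformational basins and asks three questions: how
many basins are there, which frames belong to which, and what distinguishes
them geometrically.

**Features.** Each frame is encoded as the vector of Euclidean distances
between a strided subset of CA atoms. Pairwise distances are invariant
under global rotation and translation, so no prior superposition is needed
and frames from different runs pool directly. The stride is a pure
cost/resolution trade-off: on a 1275-residue chain, stride 25 keeps 51
atoms and 1275 features instead of 812,175 for all CA pairs. Stride
counting walks positions among CA-bearing residues starting at the first,
so chains with gaps still give a deterministic selection. The bundled
213-atom miniature uses stride 5 (43 atoms, 903 features), the same
~20 %-of-residues coverage at desk scale.

**Reduction.** PCA with column-mean centring and 1/(n−1) covariance
normalization (the normalization does not affect variance ratios). The
retained dimensionality is the smallest m whose cumulative
explained-variance ratio reaches the threshold (default 0.80). Component
signs are fixed by making each component's largest-magnitude loading
positive so serialized models are bit-stable. PCA is fit separately per
system type (open-start vs closed-start trajectories are separate
landscapes).

**Clustering.** Full-covariance Gaussian mixtures fit by EM. The reduced
space is low-dimensional (2–4 here), so full covariances are affordable
and the most expressive choice. The fit contract exposes the per-iteration
log-likelihood path; EM guarantees it is non-decreasing and the test suite
enforces that on every fit. Details that matter for reproducibility:

- initialization: k-means++-style D² seeding followed by a short Lloyd
  refinement and a hard-assignment M-step, so component covariances start
  *local*. Starting all components at the global covariance lets EM drift
  into merged or near-singular optima when basins are far apart relative
  to their width — exactly the regime conformational landscapes live in.
- best of `n_init = 10` initializations (seeded `seed + i`) by final
  log-likelihood; convergence when the total log-likelihood gain drops
  below 1e-6 or after 500 iterations; covariance floor 1e-6 on diagonals.
- hard assignment by maximal posterior responsibility, ties to the lowest
  component index. Representative frames minimize Euclidean distance to
  the component mean among assigned frames, ties to the lowest frame
  index.

**Choosing K.** Two standard heuristics are computed and reported side by
side; nothing is auto-selected unless the caller asks. The silhouette
ranking uses Euclidean distances, scores singleton clusters 0, and above
20,000 frames evaluates a seeded subsample (the distance matrix is
quadratic in frames). The elbow is located on the BIC-vs-K curve as the
interior K maximizing the ratio of the incoming score drop to the outgoing
one. We initially used the discrete second difference (maximum curvature),
but it localizes poorly when the pre-elbow drops are uneven: each drop
scales with the empirical mass of the basins being resolved and the log of
their separations, so the second difference peaks at whichever early drop
happens to be largest, not at the corner. The drop-ratio form is
scale-invariant and keys on the robust signature — the first K beyond
which adding a component stops paying (the BIC drop collapses to the
penalty scale). On planted 5- and 6-basin ensembles it recovers the true K
in 10/10 seeds where the second difference managed at most 7/10. The
negative log-likelihood curve can be used instead of BIC via a flag.

**Geometry.** Superposition is a weighted Kabsch fit (proper rotations
only; scipy's `align_vectors` backend); frames are aligned on the rigid
fingers–palm–thumb core and per-domain RMSDs are computed without re-fit,
so they measure mobility relative to the core. `internal_rmsd` re-fits the
domain itself first and therefore reports pure internal flexibility; it
can never exceed the un-refit value frame-wise. The average reference
structure is the fixed point of {mean coordinates → realign frames on core
to the mean}, iterated to a 1e-4 Å change cap at 20 passes — a fixed
point, unlike a one-pass mean, is reproducible across implementations.
"Backbone" means N, CA, C where present; CA-only data degrades to CA.

**State classification.** The open/closed criterion is the per-frame
minimum CA–CA distance between two domains (default CTD–tower), with a
strict `< 8 Å` test (10 Å available). Salt bridges are cross-domain
basic-nitrogen/acidic-oxygen pairs (Lys NZ; Arg NE/NH1/NH2; His ND1/NE2 vs
Asp OD1/OD2; Glu OE1/OE2) within 4.0 Å — a common literature convention,
as no cutoff is standard — and hydrophobic contacts are side-chain
carbon–carbon pairs ≤ 4.5 Å between residues of a configurable
hydrophobic set. Both need side-chain atoms and are skipped with a warning
on CA-only data.

## The synthetic generator

`synthetic_data` emulates what the analysis must detect, not the physics
that produces it. The miniature topology has seven compact domains (atoms
on Fibonacci-sphere shells with ~3.8 Å surface spacing) whose sizes are
the real domains scaled by ~1/6 (213 atoms total) and whose centres put
the FPT core in a row with the tower below and the CTD placed so the
reference minimum CTD–tower distance is ~16 Å — the separation the
open-ring starting structure shows. The closed-like system uses the same
miniature with the CTD slid along the contact axis to a ~4.5 Å gap, since
closed-ring trajectories start in contact.

Each conformational basin is a per-domain rigid transform (rotation about
the domain centroid plus translation) with per-domain isotropic Gaussian
jitter; per-frame states follow a first-order Markov chain
`alpha*I + (1-alpha)*1 pi^T` (stationary distribution exactly `pi`,
default `alpha = 0.7`, mean dwell ~3 frames), with condition-dependent
initial distributions. One RNG per run, seeded `seed + run_index`, gives
bit-reproducible output and run independence.

The bundled study conditions: 4 conditions (apo, RNA, DNA, ternary) × 2
runs × 150 frames per system. The open-like system has five basins with
uniform occupancy 0.20, two of them in CTD–tower contact (combined mass
0.40); the closed-like system has six basins with near-uniform occupancies
(0.16–0.18), four in contact (mass 0.65) — matching the ~40 % / ~65 %
close-contact fractions the two real systems show. Design constraints the
states satisfy, in order of importance:

- contact states have a noiseless minimum CTD–tower distance ≤ 6.5 Å and
  non-contact states ≥ 11 Å, so jitter cannot flip a frame across the 8 Å
  threshold;
- state-to-state displacements act along "radial" axes (EN toward/away
  from the rest of the complex, CTD along the contact axis, small lateral
  CTD slides) because a distance feature space is first-order sensitive
  only to such motions — tangential moves of the same size barely register;
- displacement magnitudes are balanced so the basins are roughly
  equidistant in feature space and no basin is under-sampled, which is
  what makes cluster-count selection well-posed;
- EN translations (7–14 Å, plus 15–35° rotations) exceed CTD displacements
  (u_c ≈ 12 Å in contact states, 5–16 Å otherwise), which exceed tower
  motions (rotations ≤ 20°, ~2 Å RMSD), wrist (< 1 Å) and the static core,
  reproducing the EN > CTD > tower > wrist > FPT-core mobility ordering;
- internal jitter sigmas make the tower the internally softest domain
  (0.8 Å) with EN/CTD internally rigid (0.5 Å), wrist 0.3 Å, core 0.2 Å.

A separate `three_mode_trajectory` drives the EN, CTD and tower domains
along their radial axes with independent Gaussian amplitudes
(6.0/6.2/7.0 Å) chosen so the three resulting principal components carry
comparable variance: the cumulative ratio crosses 0.80 exactly at three
components (cum-2 ≈ 0.72–0.77 across seeds).

**What the generator does not emulate** — and hence what passing tests do
not show about real data: no force field, solvent or thermostat; basins
are ideal Gaussians (real basins are anharmonic and overlapping); domain
interpenetration is not prevented (only CTD–tower geometry is
controlled); transitions are memoryless with frame-scale dwell times
rather than the rare, pathway-dependent rearrangements of real
trajectories; and chains have no covalent connectivity between domains.
Recovery at ARI 1.0 therefore demonstrates the correctness of the
pipeline's contracts, not that real landscapes are this separable.

## Problem sizes and runtime

All bundled analyses run on 1200 frames × 213 atoms per system (features:
1200 × 903), chosen so the full test suite finishes in a few minutes on
one CPU while keeping ≥ 100 expected frames per basin — enough for the
per-condition population tables to be estimable to ±0.05. The acceptance
script analyses one seed per system (~1 minute); the test suite repeats
the recovery over 10 seeds per system.

## Known limitations

- The elbow is only defined for interior K of the scanned range: a true K
  at the boundary (e.g. the two-state demo scanned from K = 2) yields no
  elbow claim, by design; use the silhouette ranking there.
- `read_pdb` keeps the first chain unless a chain ID is given; hetero
  records are kept, hydrogens are not treated specially.
- DCD/XTC reading requires mdtraj and converts nm → Å; writing those
  formats is not provided (multi-model PDB is the interchange format).
- Salt-bridge/hydrophobic detection is distance-only; no angular
  hydrogen-bond criterion is implemented.
- With fewer frames than features, eigenvalues beyond rank n−1 are
  identically zero; `n_components_for_threshold(model, 1.0)` returns the
  covariance rank.
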