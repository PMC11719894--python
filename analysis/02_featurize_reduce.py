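#!/usr/bin/env python
"""Build the CA-distance feature matrices and reduce them with PCA.

Loads the runs written by 01_simulate.py, picks every 5th CA atom of the
213-atom miniature (the desk-scale analogue of stride 25 on the 1275-residue
protein), computes all pairwise distances per frame, fits PCA per system
type, and keeps the smallest component count explaining 80% of the variance.
"""

from pathlib import Path

import numpy as np

from mdscape.featurize import distance_features, pick_feature_atoms
from mdscape.reduce import fit_pca, n_components_for_threshold, project
from mdscape.structure_model import read_trajectory

STRIDE = 5
RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    for name in ("open_like", "closed_like"):
        outdir = RESULTS / name
        trajs = []
        for path in sorted((outdir / "runs").glob("*.pdb")):
            condition = path.stem.rsplit("-", 1)[0]
            trajs.append(read_trajectory(path, run_id=path.stem, condition=condition))
        atoms = pick_feature_atoms(trajs[0].topology, STRIDE)
        fm = distance_features(trajs, atoms)
        fm.save(outdir / "features")

        pca = fit_pca(fm)
        m = n_components_for_threshold(pca, 0.80)
        reduced = project(pca, fm, m)
        pca.save(outdir / "pca")
        np.savez_compressed(outdir / "scores.npz", scores=reduced.scores, m=m)

        evr = np.round(pca.explained_variance_ratio[:4], 3)
        print(f"{name}: {len(atoms)} feature atoms -> {fm.n_features} distances "
              f"over {fm.n_frames} frames")
        print(f"  leading variance ratios {evr}; {m} components reach 80%")


if __name__ == "__main__":
    main()
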