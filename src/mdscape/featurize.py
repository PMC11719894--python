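"""Strided CA selection and the frames x pairwise-distance feature matrix.

Every frame of every pooled run is described by the Euclidean distances
between a strided subset of CA atoms; with n feature atoms this yields
n(n-1)/2 features per frame (51 atoms -> 1275 features on a 1275-residue
chain at stride 25).  Runs are pooled by concatenating their frames in input
order, and each row keeps (run_id, condition, frame) metadata.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .structure_model import Structure, Trajectory, select_atoms

__all__ = [
    "FeatureMatrix",
    "pick_feature_atoms",
    "feature_count",
    "distance_features",
]


@dataclass
class FeatureMatrix:
    """Frames x pairwise-distance features with full column provenance.

    ``pair_index[j] = (a, b)`` (atom indices into the topology, a < b) defines
    column j; ``feature_atoms`` lists the selected CA atom indices; and
    ``frame_meta`` carries one (run_id, condition, frame) row per matrix row.
    """

    values: np.ndarray
    pair_index: np.ndarray  # (D, 2) int
    feature_atoms: np.ndarray
    frame_meta: pd.DataFrame

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.pair_index = np.asarray(self.pair_index, dtype=int)
        self.feature_atoms = np.asarray(self.feature_atoms, dtype=int)
        n = len(self.feature_atoms)
        if self.values.shape[1] != feature_count(n):
            raise ValueError(
                f"{self.values.shape[1]} columns inconsistent with "
                f"{n} feature atoms (expected {feature_count(n)})"
            )
        if len(self.frame_meta) != self.values.shape[0]:
            raise ValueError("frame_meta length must match the number of rows")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def save(self, prefix: str | Path) -> None:
        """Persist as ``<prefix>.npz`` plus a ``<prefix>_meta.csv`` sidecar."""
        prefix = Path(prefix)
        np.savez_compressed(
            prefix.with_suffix(".npz"),
            values=self.values,
            pair_index=self.pair_index,
            feature_atoms=self.feature_atoms,
        )
        self.frame_meta.to_csv(prefix.parent / f"{prefix.name}_meta.csv", index=False)

    @classmethod
    def load(cls, prefix: str | Path) -> "FeatureMatrix":
        prefix = Path(prefix)
        with np.load(prefix.with_suffix(".npz")) as data:
            values = data["values"]
            pair_index = data["pair_index"]
            feature_atoms = data["feature_atoms"]
        meta = pd.read_csv(prefix.parent / f"{prefix.name}_meta.csv")
        return cls(values, pair_index, feature_atoms, meta)


def pick_feature_atoms(structure: Structure, stride: int) -> np.ndarray:
    """CA atoms of every stride-th CA-bearing residue, starting at the first.

    The stride counts positions among CA-bearing residues (not raw residue
    numbers), so chains with gaps still yield a deterministic selection.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    ca = select_atoms(structure, "CA")
    if len(ca) == 0:
        raise ValueError("structure has no CA atoms")
    return ca[::stride]


def feature_count(n_atoms: int) -> int:
    """Number of unordered atom pairs, n(n-1)/2."""
    if n_atoms < 0:
        raise ValueError("n_atoms must be >= 0")
    return n_atoms * (n_atoms - 1) // 2


def distance_features(
    trajectories: Sequence[Trajectory] | Trajectory,
    atom_indices: np.ndarray,
) -> FeatureMatrix:
    """Pairwise CA-CA distances per frame, pooled over runs in input order.

    Columns are ordered lexicographically in (i, j), i < j, over positions in
    ``atom_indices``, matching ``np.triu_indices``.
    """
    if isinstance(trajectories, Trajectory):
        trajectories = [trajectories]
    if not trajectories:
        raise ValueError("need at least one trajectory")
    atom_indices = np.asarray(atom_indices, dtype=int)
    n_atoms_topo = trajectories[0].n_atoms
    for traj in trajectories:
        if traj.n_atoms != n_atoms_topo:
            raise ValueError("all trajectories must share one topology")
    if len(atom_indices) and (
        atom_indices.min() < 0 or atom_indices.max() >= n_atoms_topo
    ):
        raise IndexError("atom index out of range for the shared topology")

    ii, jj = np.triu_indices(len(atom_indices), k=1)
    blocks = []
    meta_rows = []
    for traj in trajectories:
        sub = traj.coords[:, atom_indices, :]
        diff = sub[:, ii, :] - sub[:, jj, :]
        blocks.append(np.linalg.norm(diff, axis=2))
        meta_rows.append(
            pd.DataFrame(
                {
                    "run_id": traj.run_id,
                    "condition": traj.condition,
                    "frame": np.arange(traj.n_frames),
                }
            )
        )
    values = np.concatenate(blocks, axis=0) if blocks else np.empty((0, len(ii)))
    pair_index = np.stack([atom_indices[ii], atom_indices[jj]], axis=1)
    meta = pd.concat(meta_rows, ignore_index=True)
    return FeatureMatrix(values, pair_index, atom_indices, meta)
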