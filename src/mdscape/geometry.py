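"""Superposition, per-domain RMSD, interdomain distances, contact detection.

All RMSD analyses follow the rigid-core convention: frames are first
superposed on the fingers-palm-thumb (FPT) core by a least-squares Kabsch
fit, and per-domain RMSDs are then computed *without* re-fitting on the
domain, so they measure the domain's mobility relative to the core.
``internal_rmsd`` instead superposes the domain on itself first, removing its
rigid-body motion and measuring only internal flexibility.

State classification uses the minimum CA-CA distance between two domains
(typically CTD and tower): frames with distance strictly below the threshold
(default 8 A, optionally 10 A) are in the closed-contact state.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .structure_model import Structure, Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "SuperpositionResult",
    "RMSDSeries",
    "DistanceSeries",
    "kabsch",
    "superpose_on_core",
    "average_structure",
    "domain_rmsd",
    "internal_rmsd",
    "min_interdomain_distance",
    "fraction_below",
    "classify_open_closed",
    "find_salt_bridges",
    "find_hydrophobic_contacts",
]

#: Side-chain donor/acceptor atoms for salt-bridge detection.
BASIC_NITROGENS = {"LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2"), "HIS": ("ND1", "NE2")}
ACIDIC_OXYGENS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}

#: Default hydrophobic residue set for side-chain carbon contacts.
HYDROPHOBIC_RESIDUES = {"ALA", "VAL", "LEU", "ILE", "PRO", "PHE", "MET", "TRP"}


@dataclass
class SuperpositionResult:
    """Proper rotation (det +1), translation and RMSD over the fit atoms."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)
    rmsd_on_fit_atoms: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class RMSDSeries:
    """Per-frame RMSD (A) of one domain against one reference kind."""

    values: np.ndarray
    domain: str = ""
    reference_kind: str = "initial"
    mean: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("RMSD values must be non-negative")
        self.mean = float(self.values.mean())
        self.sd = float(self.values.std(ddof=0))


@dataclass
class DistanceSeries:
    """Per-frame minimum CA-CA distance (A) between two domains."""

    values: np.ndarray
    pair: tuple[str, str] = ("", "")

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def kabsch(
    mobile_coords: np.ndarray,
    reference_coords: np.ndarray,
    weights: np.ndarray | None = None,
) -> SuperpositionResult:
    """Least-squares optimal proper rotation + translation (reflection excluded).

    Finds R, t minimizing ``sum_i w_i |ref_i - (R mobile_i + t)|^2``; the
    backend is scipy's ``Rotation.align_vectors`` on the centred point sets.
    Collinear point sets are flagged with a warning (the in-plane rotation is
    then underdetermined).
    """
    mobile = np.asarray(mobile_coords, dtype=float)
    reference = np.asarray(reference_coords, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must both be (n, 3)")
    n = len(mobile)
    if n < 3:
        raise ValueError("superposition requires at least 3 points")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    wsum = w.sum()

    mob_centroid = (w[:, None] * mobile).sum(axis=0) / wsum
    ref_centroid = (w[:, None] * reference).sum(axis=0) / wsum
    mob_c = mobile - mob_centroid
    ref_c = reference - ref_centroid

    sv = np.linalg.svd(mob_c, compute_uv=False)
    if sv[1] < 1e-8 * max(sv[0], 1e-30):
        warnings.warn("mobile points are (nearly) collinear; rotation is underdetermined")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # align_vectors warns on exact fits
        rot, _ = Rotation.align_vectors(ref_c, mob_c, weights=w)
    matrix = rot.as_matrix()
    translation = ref_centroid - matrix @ mob_centroid
    fitted = mobile @ matrix.T + translation
    rmsd = float(np.sqrt((w[:, None] * (fitted - reference) ** 2).sum() / wsum))
    return SuperpositionResult(matrix, translation, rmsd)


def superpose_on_core(
    trajectory: Trajectory,
    core_atom_indices: np.ndarray,
    reference_structure: Structure,
) -> Trajectory:
    """Align every frame on the core atoms; the transform applies to all atoms."""
    core = np.asarray(core_atom_indices, dtype=int)
    if core.max(initial=-1) >= trajectory.n_atoms or core.max(initial=-1) >= reference_structure.n_atoms:
        raise IndexError("core atom index out of range")
    ref_core = reference_structure.coords[core]
    aligned = np.empty_like(trajectory.coords)
    for f in range(trajectory.n_frames):
        fit = kabsch(trajectory.coords[f, core], ref_core)
        aligned[f] = fit.apply(trajectory.coords[f])
    return Trajectory(
        topology=trajectory.topology,
        coords=aligned,
        run_id=trajectory.run_id,
        condition=trajectory.condition,
        system_type=trajectory.system_type,
    )


def average_structure(
    trajectory: Trajectory,
    core_atom_indices: np.ndarray,
    tol: float = 1e-4,
    max_iter: int = 20,
) -> Structure:
    """Iterated mean structure: mean -> realign frames on core -> mean.

    Iterates to a fixed point (maximum coordinate change below ``tol`` A, at
    most ``max_iter`` passes); non-convergence is logged and the last iterate
    returned.
    """
    coords = trajectory.coords
    mean = coords.mean(axis=0)
    for _ in range(max_iter):
        reference = trajectory.topology.with_coords(mean)
        realigned = superpose_on_core(
            Trajectory(trajectory.topology, coords), core_atom_indices, reference
        )
        new_mean = realigned.coords.mean(axis=0)
        change = np.abs(new_mean - mean).max()
        mean = new_mean
        if change < tol:
            break
    else:
        logger.warning("average_structure did not converge (last change %.2e A)", change)
    return trajectory.topology.with_coords(mean, identifier="average")


# ---------------------------------------------------------------------------
# RMSD
# ---------------------------------------------------------------------------

def _reference_coords(reference: Structure | np.ndarray) -> np.ndarray:
    return reference.coords if isinstance(reference, Structure) else np.asarray(reference, dtype=float)


def domain_rmsd(
    aligned_trajectory: Trajectory,
    reference: Structure | np.ndarray,
    domain_atom_indices: np.ndarray,
    domain: str = "",
    reference_kind: str = "initial",
) -> RMSDSeries:
    """Per-frame RMSD over the domain atoms, with NO re-fit on the domain.

    The trajectory must already be aligned (on the rigid core); the series
    therefore measures the domain's mobility relative to that core.
    """
    idx = np.asarray(domain_atom_indices, dtype=int)
    if len(idx) == 0:
        raise ValueError("empty domain selection")
    ref = _reference_coords(reference)[idx]
    dev = aligned_trajectory.coords[:, idx, :] - ref
    values = np.sqrt((dev**2).sum(axis=2).mean(axis=1))
    return RMSDSeries(values, domain=domain, reference_kind=reference_kind)


def internal_rmsd(
    trajectory: Trajectory,
    domain_atom_indices: np.ndarray,
    reference: Structure | np.ndarray,
    domain: str = "",
) -> RMSDSeries:
    """Per-frame RMSD after superposing the domain itself onto the reference.

    Rigid-body motion of the domain is removed, so the series measures
    internal flexibility only; frame-wise it can never exceed
    :func:`domain_rmsd`.
    """
    idx = np.asarray(domain_atom_indices, dtype=int)
    if len(idx) < 3:
        raise ValueError("internal RMSD needs at least 3 domain atoms")
    ref = _reference_coords(reference)[idx]
    values = np.empty(trajectory.n_frames)
    for f in range(trajectory.n_frames):
        values[f] = kabsch(trajectory.coords[f, idx], ref).rmsd_on_fit_atoms
    return RMSDSeries(values, domain=domain, reference_kind="internal")


# ---------------------------------------------------------------------------
# Interdomain distances and state classification
# ---------------------------------------------------------------------------

def min_interdomain_distance(
    trajectory: Trajectory,
    domain_a_indices: np.ndarray,
    domain_b_indices: np.ndarray,
    pair: tuple[str, str] = ("", ""),
) -> DistanceSeries:
    """Per-frame minimum distance over all cross-domain atom pairs."""
    idx_a = np.asarray(domain_a_indices, dtype=int)
    idx_b = np.asarray(domain_b_indices, dtype=int)
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise ValueError("both selections must be non-empty")
    if np.intersect1d(idx_a, idx_b).size:
        raise ValueError("selections overlap; interdomain distance is undefined")
    values = np.empty(trajectory.n_frames)
    for f in range(trajectory.n_frames):
        values[f] = cdist(trajectory.coords[f, idx_a], trajectory.coords[f, idx_b]).min()
    return DistanceSeries(values, pair=pair)


def fraction_below(distance_series: DistanceSeries | np.ndarray, threshold: float) -> float:
    """Fraction of frames with distance strictly below the threshold."""
    values = (
        distance_series.values
        if isinstance(distance_series, DistanceSeries)
        else np.asarray(distance_series, dtype=float)
    )
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if len(values) == 0:
        raise ValueError("empty distance series")
    return float((values < threshold).mean())


def classify_open_closed(
    distance_series: DistanceSeries | np.ndarray,
    threshold: float = 8.0,
) -> np.ndarray:
    """Per-frame state: ``closed`` if distance < threshold (strict), else ``open``."""
    values = (
        distance_series.values
        if isinstance(distance_series, DistanceSeries)
        else np.asarray(distance_series, dtype=float)
    )
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return np.where(values < threshold, "closed", "open")


# ---------------------------------------------------------------------------
# Contacts
# ---------------------------------------------------------------------------

def _domain_mask(structure: Structure, domain_map, domain: str) -> np.ndarray:
    if domain not in domain_map and domain != "FPT":
        raise KeyError(f"unknown domain {domain!r}")
    mask = np.zeros(structure.n_atoms, dtype=bool)
    for start, end in domain_map.intervals_for(domain):
        mask |= (structure.residue_indices >= start) & (structure.residue_indices <= end)
    return mask


def find_salt_bridges(
    structure: Structure,
    domain_map,
    domain_a: str,
    domain_b: str,
    cutoff: float = 4.0,
) -> pd.DataFrame:
    """Cross-domain basic-N / acidic-O pairs within the cutoff.

    Basic nitrogens: Lys NZ; Arg NE/NH1/NH2; His ND1/NE2.  Acidic oxygens:
    Asp OD1/OD2; Glu OE1/OE2.  On CA-only data a warning is emitted and an
    empty table returned.  The result is symmetric in the domain order: rows
    always report the basic partner first.
    """
    mask_a = _domain_mask(structure, domain_map, domain_a)
    mask_b = _domain_mask(structure, domain_map, domain_b)

    def _sites(table: dict[str, tuple[str, ...]], mask: np.ndarray) -> np.ndarray:
        hits = []
        for i in np.flatnonzero(mask):
            allowed = table.get(structure.residue_names[i], ())
            if structure.atom_names[i] in allowed:
                hits.append(i)
        return np.asarray(hits, dtype=int)

    if np.all(structure.atom_names == "CA"):
        warnings.warn("salt-bridge detection skipped: structure has CA atoms only")
        return _contact_frame([])

    rows = []
    for basic_mask, acidic_mask in ((mask_a, mask_b), (mask_b, mask_a)):
        basics = _sites(BASIC_NITROGENS, basic_mask)
        acidics = _sites(ACIDIC_OXYGENS, acidic_mask)
        if len(basics) == 0 or len(acidics) == 0:
            continue
        dists = cdist(structure.coords[basics], structure.coords[acidics])
        for i, j in zip(*np.nonzero(dists <= cutoff)):
            bi, ai = basics[i], acidics[j]
            rows.append(
                (
                    int(structure.residue_indices[bi]),
                    structure.residue_names[bi],
                    structure.atom_names[bi],
                    int(structure.residue_indices[ai]),
                    structure.residue_names[ai],
                    structure.atom_names[ai],
                    float(dists[i, j]),
                )
            )
    return _contact_frame(sorted(set(rows)))


def _contact_frame(rows) -> pd.DataFrame:
    return pd.DataFrame(
        rows,
        columns=["res_basic", "name_basic", "atom_basic", "res_acidic", "name_acidic", "atom_acidic", "distance"],
    )


def find_hydrophobic_contacts(
    structure: Structure,
    domain_map,
    domain_a: str,
    domain_b: str,
    cutoff: float = 4.5,
    hydrophobic_set: set[str] | None = None,
) -> pd.DataFrame:
    """Cross-domain hydrophobic residue pairs by side-chain carbon proximity.

    A pair qualifies when both residues belong to the hydrophobic set
    (default Ala/Val/Leu/Ile/Pro/Phe/Met/Trp, extendable) and any side-chain
    carbon-carbon distance is <= cutoff.  Pairs are reported once with the
    minimum distance, ordered by residue index, so the result is symmetric in
    the domain order.
    """
    hydro = HYDROPHOBIC_RESIDUES if hydrophobic_set is None else set(hydrophobic_set)
    known = set(BASIC_NITROGENS) | set(ACIDIC_OXYGENS) | {
        "ALA", "VAL", "LEU", "ILE", "PRO", "PHE", "MET", "TRP", "GLY", "SER",
        "THR", "CYS", "TYR", "ASN", "GLN",
    }
    for res in hydro - known:
        warnings.warn(f"unknown residue {res!r} in hydrophobic set; ignored")
    hydro &= known

    def _sidechain_carbons(mask: np.ndarray) -> np.ndarray:
        hits = []
        for i in np.flatnonzero(mask):
            name = structure.atom_names[i]
            if (
                structure.residue_names[i] in hydro
                and name.startswith("C")
                and name not in ("C", "CA")
            ):
                hits.append(i)
        return np.asarray(hits, dtype=int)

    carbons_a = _sidechain_carbons(_domain_mask(structure, domain_map, domain_a))
    carbons_b = _sidechain_carbons(_domain_mask(structure, domain_map, domain_b))
    if len(carbons_a) == 0 or len(carbons_b) == 0:
        return pd.DataFrame(columns=["res_i", "name_i", "res_j", "name_j", "distance"])

    dists = cdist(structure.coords[carbons_a], structure.coords[carbons_b])
    best: dict[tuple[int, int], tuple[str, str, float]] = {}
    for i, j in zip(*np.nonzero(dists <= cutoff)):
        ai, bj = carbons_a[i], carbons_b[j]
        ri, rj = int(structure.residue_indices[ai]), int(structure.residue_indices[bj])
        if ri == rj:
            continue
        ni, nj = structure.residue_names[ai], structure.residue_names[bj]
        if ri > rj:
            ri, rj, ni, nj = rj, ri, nj, ni
        d = float(dists[i, j])
        if (ri, rj) not in best or d < best[(ri, rj)][2]:
            best[(ri, rj)] = (ni, nj, d)
    rows = [
        (ri, ni, rj, nj, d)
        for (ri, rj), (ni, nj, d) in sorted(best.items())
    ]
    return pd.DataFrame(rows, columns=["res_i", "name_i", "res_j", "name_j", "distance"])
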