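"""Synthetic multidomain CA-only ensembles with planted conformational states.

The generator emulates the qualitative behaviour of a seven-domain
polymerase-like complex observed in long MD runs: a rigid fingers-palm-thumb
core, terminal domains (EN, CTD) undergoing large rigid-body translations and
rotations, an internally flexible tower domain, and switching between a small
number of conformational basins with condition-dependent occupancies.  Each
basin is a :class:`StateSpec`: one rigid transform per domain (rotation about
the domain centroid plus a translation) and a per-domain isotropic Gaussian
jitter.  A first-order Markov chain over basins produces per-frame state
labels, which are returned as :class:`GroundTruth` so every downstream stage
(featurization, PCA, clustering, geometry) can be validated against the
planted truth.

No force field is claimed: the generator reproduces the geometry of the
motions, not their energetics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .structure_model import DomainMap, Structure, Trajectory, write_trajectory

__all__ = [
    "DomainMotion",
    "StateSpec",
    "EnsembleSpec",
    "GroundTruth",
    "build_toy_topology",
    "default_topology",
    "sample_state_sequence",
    "generate_trajectory",
    "state_coordinates",
    "state_contact_flags",
    "sticky_transition",
    "openlike_ensemble",
    "closedlike_ensemble",
    "two_state_demo",
    "three_mode_trajectory",
    "save_run",
]


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass
class DomainMotion:
    """Rigid transform of one domain: rotation about its centroid + translation.

    ``rotation_angle`` is in degrees about ``rotation_axis`` (normalized
    internally); ``translation`` is in A.
    """

    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rotation_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    rotation_angle: float = 0.0

    def __post_init__(self):
        if self.rotation_angle != 0.0 and np.linalg.norm(self.rotation_axis) == 0:
            raise ValueError("rotation axis must be non-zero when angle != 0")

    def rotation(self) -> Rotation:
        if self.rotation_angle == 0.0:
            return Rotation.identity()
        axis = np.asarray(self.rotation_axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        return Rotation.from_rotvec(np.deg2rad(self.rotation_angle) * axis)


@dataclass
class StateSpec:
    """One conformational basin: per-domain motions and jitter sigmas (A)."""

    motions: dict[str, DomainMotion] = field(default_factory=dict)
    jitter: dict[str, float] = field(default_factory=dict)
    name: str = ""

    def __post_init__(self):
        for domain, sigma in self.jitter.items():
            if sigma < 0:
                raise ValueError(f"jitter sigma for {domain!r} must be >= 0")


@dataclass
class EnsembleSpec:
    """Full generator specification for one system type.

    ``runs_per_condition`` maps condition label -> number of runs and
    ``initial_distribution`` maps condition -> distribution over the K states
    for the first frame of each run; subsequent frames follow ``transition``.
    """

    topology: Structure
    domain_map: DomainMap
    states: list[StateSpec]
    transition: np.ndarray
    frames_per_run: int
    runs_per_condition: dict[str, int]
    initial_distribution: dict[str, np.ndarray]
    seed: int = 0
    system_type: str = "custom"

    def __post_init__(self):
        self.transition = np.asarray(self.transition, dtype=float)
        k = len(self.states)
        if k < 1:
            raise ValueError("need at least one state")
        if self.transition.shape != (k, k):
            raise ValueError(f"transition matrix must be {k}x{k}")
        _check_stochastic(self.transition)
        if self.frames_per_run < 1:
            raise ValueError("frames_per_run must be >= 1")
        for cond, dist in self.initial_distribution.items():
            dist = np.asarray(dist, dtype=float)
            if dist.shape != (k,) or abs(dist.sum() - 1.0) > 1e-9 or np.any(dist < 0):
                raise ValueError(f"invalid initial distribution for {cond!r}")
            self.initial_distribution[cond] = dist
        known = set(self.domain_map.names())
        for state in self.states:
            unknown = set(state.motions) | set(state.jitter)
            unknown -= known
            if unknown:
                raise ValueError(f"state references unknown domains: {sorted(unknown)}")

    @property
    def n_states(self) -> int:
        return len(self.states)

    def to_yaml(self, path: str | Path) -> None:
        """Persist the spec (without coordinates) for provenance."""
        payload = {
            "system_type": self.system_type,
            "seed": int(self.seed),
            "frames_per_run": int(self.frames_per_run),
            "runs_per_condition": {k: int(v) for k, v in self.runs_per_condition.items()},
            "transition": self.transition.tolist(),
            "initial_distribution": {
                k: np.asarray(v).tolist() for k, v in self.initial_distribution.items()
            },
            "domain_map": {k: list(v) for k, v in self.domain_map.intervals.items()},
            "states": [
                {
                    "name": s.name,
                    "jitter": {k: float(v) for k, v in s.jitter.items()},
                    "motions": {
                        d: {
                            "translation": list(map(float, m.translation)),
                            "rotation_axis": list(map(float, m.rotation_axis)),
                            "rotation_angle": float(m.rotation_angle),
                        }
                        for d, m in s.motions.items()
                    },
                }
                for s in self.states
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh)


@dataclass
class GroundTruth:
    """Planted per-frame state labels for one generated run."""

    labels: np.ndarray
    run_id: str
    condition: str
    spec: EnsembleSpec | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if self.spec is not None and (
            self.labels.min(initial=0) < 0
            or self.labels.max(initial=0) >= self.spec.n_states
        ):
            raise ValueError("labels out of range [0, K)")


def _check_stochastic(matrix: np.ndarray) -> None:
    if np.any(matrix < 0):
        raise ValueError("transition matrix entries must be >= 0")
    rows = matrix.sum(axis=1)
    if not np.allclose(rows, 1.0, atol=1e-12, rtol=0):
        raise ValueError(f"transition matrix rows must sum to 1, got {rows}")


# ---------------------------------------------------------------------------
# Toy topology
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int, radius: float) -> np.ndarray:
    """n roughly evenly spaced points on a sphere (compact domain stand-in)."""
    if n == 1:
        return np.zeros((1, 3))
    k = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (k + 0.5) / n
    theta = np.pi * (1.0 + 5.0**0.5) * k
    r_xy = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    pts = np.stack([r_xy * np.cos(theta), r_xy * np.sin(theta), z], axis=1)
    return radius * pts


def build_toy_topology(
    domain_sizes: Mapping[str, int],
    centers: Mapping[str, Sequence[float]] | None = None,
    identifier: str = "toy",
) -> tuple[Structure, DomainMap]:
    """CA-only chain with one compact cluster of atoms per domain.

    Domains are numbered consecutively in the given order; each domain's atoms
    lie on a sphere of radius chosen so the surface spacing is ~3.8 A (a CA-CA
    step), centred at the configured (or sequentially laid out) centre, so
    interdomain minimum distances are controllable.
    """
    if not domain_sizes:
        raise ValueError("domain list must not be empty")
    for name, size in domain_sizes.items():
        if size < 1:
            raise ValueError(f"domain {name!r} must have >= 1 residue")

    radii = {
        name: max(2.0, 3.8 * np.sqrt(size / (4.0 * np.pi)))
        for name, size in domain_sizes.items()
    }
    if centers is None:
        centers = {}
        x = 0.0
        prev_r = None
        for name in domain_sizes:
            if prev_r is not None:
                x += prev_r + radii[name] + 6.0
            centers[name] = (x, 0.0, 0.0)
            prev_r = radii[name]

    res_idx: list[int] = []
    res_names: list[str] = []
    atom_names: list[str] = []
    coords: list[np.ndarray] = []
    intervals: dict[str, tuple[int, int]] = {}
    next_res = 1
    for name, size in domain_sizes.items():
        pts = _fibonacci_sphere(size, radii[name]) + np.asarray(centers[name], float)
        intervals[name] = (next_res, next_res + size - 1)
        for i in range(size):
            res_idx.append(next_res + i)
            res_names.append("ALA")
            atom_names.append("CA")
            coords.append(pts[i])
        next_res += size

    structure = Structure(res_idx, res_names, atom_names, np.array(coords), identifier)
    return structure, DomainMap(intervals)


#: Sizes of the seven-domain miniature (~1/6 of the real residue counts).
DEFAULT_DOMAIN_SIZES: dict[str, int] = {
    "EN": 40,
    "tower": 33,
    "fingers": 20,
    "palm": 36,
    "thumb": 15,
    "wrist": 33,
    "CTD": 36,
}

#: Centres place the FPT core in a row, wrist above it, tower below the
#: fingers, EN peripheral, and CTD ~16 A (minimum CA-CA) from the tower,
#: matching the starting-geometry separation the analyses probe.
DEFAULT_CENTERS: dict[str, tuple[float, float, float]] = {
    "EN": (-18.0, -2.0, 8.0),
    "tower": (0.0, -16.0, 0.0),
    "fingers": (0.0, 0.0, 0.0),
    "palm": (12.0, 0.0, 0.0),
    "thumb": (24.0, 0.0, 0.0),
    "wrist": (12.0, 14.0, 0.0),
    "CTD": (24.0, -30.0, 8.0),
}


def default_topology() -> tuple[Structure, DomainMap]:
    """The 213-atom seven-domain miniature used by the bundled analyses."""
    return build_toy_topology(DEFAULT_DOMAIN_SIZES, DEFAULT_CENTERS, identifier="miniature")


def closed_topology() -> tuple[Structure, DomainMap]:
    """Miniature whose reference has the CTD in contact with the tower.

    Models the closed-ring starting geometry (minimal CTD-tower distance,
    ~4.5 A), obtained from :func:`default_topology` by sliding the CTD along
    the contact axis.
    """
    topology, dmap = default_topology()
    shift = contact_translation(topology, dmap, gap=4.5)
    coords = topology.coords.copy()
    coords[dmap.atom_indices(topology, "CTD")] += shift
    return topology.with_coords(coords, identifier="miniature-closed"), dmap


# ---------------------------------------------------------------------------
# Markov chain
# ---------------------------------------------------------------------------

def sample_state_sequence(
    transition: np.ndarray,
    n_frames: int,
    initial_distribution: np.ndarray,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Sample a label sequence from a first-order Markov chain."""
    transition = np.asarray(transition, dtype=float)
    _check_stochastic(transition)
    initial = np.asarray(initial_distribution, dtype=float)
    if initial.ndim != 1 or len(initial) != transition.shape[0]:
        raise ValueError("initial distribution size must match the chain")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    labels = np.empty(n_frames, dtype=int)
    cum_init = np.cumsum(initial)
    cum_rows = np.cumsum(transition, axis=1)
    labels[0] = np.searchsorted(cum_init, rng.random())
    u = rng.random(n_frames - 1)
    for t in range(1, n_frames):
        labels[t] = np.searchsorted(cum_rows[labels[t - 1]], u[t - 1])
    return labels


def stationary_distribution(transition: np.ndarray) -> np.ndarray:
    """Stationary distribution pi with pi P = pi (left eigenvector)."""
    transition = np.asarray(transition, dtype=float)
    vals, vecs = np.linalg.eig(transition.T)
    i = np.argmin(np.abs(vals - 1.0))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def sticky_transition(pi: Sequence[float], alpha: float = 0.9) -> np.ndarray:
    """Transition matrix ``alpha*I + (1-alpha)*1 pi^T`` with stationary ``pi``."""
    pi = np.asarray(pi, dtype=float)
    pi = pi / pi.sum()
    k = len(pi)
    return alpha * np.eye(k) + (1.0 - alpha) * np.tile(pi, (k, 1))


# ---------------------------------------------------------------------------
# Trajectory generation
# ---------------------------------------------------------------------------

def state_coordinates(spec: EnsembleSpec, state_index: int) -> np.ndarray:
    """Noiseless coordinates of one state: per-domain rigid transforms applied."""
    state = spec.states[state_index]
    coords = spec.topology.coords.copy()
    for domain, motion in state.motions.items():
        idx = spec.domain_map.atom_indices(spec.topology, domain, atom_name="CA")
        if len(idx) == 0:
            raise ValueError(f"domain {domain!r} selects no atoms")
        ref = spec.topology.coords[idx]
        centroid = ref.mean(axis=0)
        rotated = motion.rotation().apply(ref - centroid) + centroid
        coords[idx] = rotated + np.asarray(motion.translation, dtype=float)
    return coords


def _atom_sigmas(spec: EnsembleSpec, state: StateSpec) -> np.ndarray:
    sigmas = np.zeros(spec.topology.n_atoms)
    for domain, sigma in state.jitter.items():
        idx = spec.domain_map.atom_indices(spec.topology, domain, atom_name="CA")
        sigmas[idx] = sigma
    return sigmas


def generate_trajectory(spec: EnsembleSpec) -> list[tuple[Trajectory, GroundTruth]]:
    """Generate all runs of an ensemble; bit-reproducible for a given seed.

    Each run uses its own ``default_rng(spec.seed + run_index)`` (run_index
    counts globally across conditions) so runs are independent yet
    reproducible, and adding runs does not perturb earlier ones.
    """
    state_coords = np.stack([state_coordinates(spec, k) for k in range(spec.n_states)])
    sigma_table = np.stack([_atom_sigmas(spec, s) for s in spec.states])

    out: list[tuple[Trajectory, GroundTruth]] = []
    run_index = 0
    for condition, n_runs in spec.runs_per_condition.items():
        initial = spec.initial_distribution[condition]
        for r in range(n_runs):
            rng = np.random.default_rng(spec.seed + run_index)
            labels = sample_state_sequence(
                spec.transition, spec.frames_per_run, initial, rng
            )
            coords = state_coords[labels].copy()
            sigmas = sigma_table[labels]  # (frames, atoms)
            if np.any(sigmas > 0):
                coords += rng.standard_normal(coords.shape) * sigmas[:, :, None]
            run_id = f"{condition}-{r}"
            traj = Trajectory(
                topology=spec.topology,
                coords=coords,
                run_id=run_id,
                condition=condition,
                system_type=spec.system_type,
            )
            out.append((traj, GroundTruth(labels, run_id, condition, spec)))
            run_index += 1
    return out


def state_contact_flags(
    spec: EnsembleSpec,
    domain_a: str = "CTD",
    domain_b: str = "tower",
    threshold: float = 8.0,
) -> np.ndarray:
    """Per-state flag: noiseless minimum CA-CA distance A-B below threshold."""
    idx_a = spec.domain_map.atom_indices(spec.topology, domain_a)
    idx_b = spec.domain_map.atom_indices(spec.topology, domain_b)
    flags = np.zeros(spec.n_states, dtype=bool)
    for k in range(spec.n_states):
        coords = state_coordinates(spec, k)
        flags[k] = cdist(coords[idx_a], coords[idx_b]).min() < threshold
    return flags


def contact_translation(
    structure: Structure,
    domain_map: DomainMap,
    mobile: str = "CTD",
    target: str = "tower",
    gap: float = 3.5,
) -> np.ndarray:
    """Translation of ``mobile`` along the centroid line giving min distance ~gap.

    Solved by bisection on the translation magnitude; used to construct
    contact states whose minimum interdomain distance is below the contact
    threshold by a safe margin.
    """
    idx_m = domain_map.atom_indices(structure, mobile)
    idx_t = domain_map.atom_indices(structure, target)
    pos_m = structure.coords[idx_m]
    pos_t = structure.coords[idx_t]
    direction = pos_t.mean(axis=0) - pos_m.mean(axis=0)
    dist = np.linalg.norm(direction)
    direction = direction / dist

    def min_dist(scale: float) -> float:
        return cdist(pos_m + scale * direction, pos_t).min()

    lo, hi = 0.0, dist
    if min_dist(lo) <= gap:
        return np.zeros(3)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if min_dist(mid) > gap:
            lo = mid
        else:
            hi = mid
    return hi * direction


# ---------------------------------------------------------------------------
# Bundled study conditions
# ---------------------------------------------------------------------------

#: Internal-jitter sigmas (A): tower is internally the most flexible domain,
#: EN and CTD are internally rigid (they move as rigid bodies), the FPT core
#: is stiffest.
DEFAULT_JITTER: dict[str, float] = {
    "EN": 0.5,
    "tower": 0.8,
    "fingers": 0.2,
    "palm": 0.2,
    "thumb": 0.2,
    "wrist": 0.3,
    "CTD": 0.5,
}

_DM = DomainMotion


def _motion_axes(topology: Structure, dmap: DomainMap):
    """Displacement axes that actually change interdomain distances.

    ``u_en``: unit vector from the centroid of all non-EN domains through the
    EN centroid (EN moving along it changes its distances to every other
    domain roughly linearly — tangential moves barely register in a
    distance-based feature space).  ``uhat_c``: unit vector from the CTD
    centroid toward the tower centroid (the contact axis).
    """
    others = [d for d in dmap.names() if d != "EN"]
    rest = np.mean(
        [topology.coords[dmap.atom_indices(topology, d)].mean(axis=0) for d in others],
        axis=0,
    )
    en_centroid = topology.coords[dmap.atom_indices(topology, "EN")].mean(axis=0)
    u_en = en_centroid - rest
    u_en /= np.linalg.norm(u_en)
    ctd = topology.coords[dmap.atom_indices(topology, "CTD")].mean(axis=0)
    tower = topology.coords[dmap.atom_indices(topology, "tower")].mean(axis=0)
    uhat_c = tower - ctd
    uhat_c /= np.linalg.norm(uhat_c)
    return u_en, uhat_c


def _openlike_states(topology: Structure, dmap: DomainMap) -> list[StateSpec]:
    j = DEFAULT_JITTER
    u_en, uhat_c = _motion_axes(topology, dmap)
    u_c = contact_translation(topology, dmap)

    def en(a, lat=(0.0, 0.0, 0.0)):
        return tuple(a * u_en + np.asarray(lat, float))

    def ctd_away(b, lat=(0.0, 0.0, 0.0)):
        return tuple(-b * uhat_c + np.asarray(lat, float))

    return [
        StateSpec({}, dict(j), name="start-like"),
        StateSpec(
            {
                "EN": _DM(en(-10, (0, 2, 1)), (0, 0, 1), 25),
                "CTD": _DM(tuple(u_c), (1, 0, 0), 15),
                "tower": _DM((0, 0, 0), (0, 1, 0), 10),
                "wrist": _DM((0.8, 0, 0)),
            },
            dict(j),
            name="CTD-tower contact",
        ),
        StateSpec(
            {
                "EN": _DM(en(15, (0, -2, 2)), (1, 1, 0), 30),
                "CTD": _DM(ctd_away(6, (1, 1, 0))),
                "tower": _DM((1, 1, 0), (0, 1, 0), -15),
                "wrist": _DM((0, 0.8, 0)),
            },
            dict(j),
            name="EN detached",
        ),
        StateSpec(
            {
                "EN": _DM(en(13, (0, 3, -1)), (0, 1, 0), 20),
                "CTD": _DM(tuple(u_c + np.array([-1.0, 1.0, -1.0])), (0, 0, 1), -20),
                "tower": _DM((0, -2, 1), (1, 0, 0), 20),
                "wrist": _DM((0, 0, 1)),
            },
            dict(j),
            name="CTD wedged",
        ),
        StateSpec(
            {
                "EN": _DM(en(-11, (0, -2, -2)), (0, 0, 1), -35),
                "CTD": _DM(ctd_away(7, (0, 1, 2))),
                "tower": _DM((-1, 0, 2), (0, 0, 1), 8),
                "wrist": _DM((0.6, 0.6, 0)),
            },
            dict(j),
            name="elongated open",
        ),
    ]


def _closedlike_states(topology: Structure, dmap: DomainMap) -> list[StateSpec]:
    # The closed-like reference already has the CTD in contact with the tower:
    # "contact" states keep the CTD pinned there (varying EN position and a
    # small lateral CTD slide) while "open-type" states pull it away along the
    # contact axis.  State-to-state displacements are balanced so the basins
    # are roughly equidistant in the distance-feature space.
    j = DEFAULT_JITTER
    u_en, uhat_c = _motion_axes(topology, dmap)
    perp = np.cross(uhat_c, [0.0, 0.0, 1.0])
    perp /= np.linalg.norm(perp)

    def en(a, lat=(0.0, 0.0, 0.0)):
        return tuple(a * u_en + np.asarray(lat, float))

    def ctd_away(b, lat=(0.0, 0.0, 0.0)):
        return tuple(-b * uhat_c + np.asarray(lat, float))

    def ctd_slide(s):
        return tuple(s * perp)

    return [
        StateSpec(
            {
                "EN": _DM(en(-9, (0, 4, 2)), (0, 0, 1), 20),
                "CTD": _DM((0, 0, 0), (0, 1, 0), 10),
                "tower": _DM((0, 0, 0), (0, 1, 0), 12),
            },
            dict(j),
            name="contact along hairpin",
        ),
        StateSpec(
            {
                "EN": _DM(en(-5, (0, -5, 3))),
                "CTD": _DM(ctd_away(9, (0, 1, -1))),
                "tower": _DM((0, -2, 0), (0, 0, 1), -20),
                "wrist": _DM((0.5, 0, 0)),
            },
            dict(j),
            name="open-type toward wrist",
        ),
        StateSpec(
            {
                "EN": _DM(en(9, (0, 4, -4)), (1, 0, 0), 25),
                "CTD": _DM(ctd_away(14, (2, 1, 1)), (1, 0, 0), -15),
                "tower": _DM((0, 0, 0), (0, 1, 0), 6),
                "wrist": _DM((0, 0.7, 0)),
            },
            dict(j),
            name="CTD at wrist end",
        ),
        StateSpec(
            {
                "EN": _DM(en(-1, (0, -6, -2)), (0, 1, 0), 15),
                "CTD": _DM(ctd_slide(-3.5)),
                "tower": _DM((1, 0, -1), (1, 0, 0), -10),
                "wrist": _DM((0, 0, 0.8)),
            },
            dict(j),
            name="tight contact",
        ),
        StateSpec(
            {
                "EN": _DM(en(6, (0, 5, -3)), (0, 1, 0), -30),
                "CTD": _DM(ctd_slide(3.5)),
                "tower": _DM((0, 1, 1), (0, 1, 0), 18),
                "wrist": _DM((0.4, 0.4, 0)),
            },
            dict(j),
            name="contact, EN swung out",
        ),
        StateSpec(
            {
                "EN": _DM(en(13, (0, -4, 4))),
                "CTD": _DM(ctd_slide(-3.5), (0, 0, 1), 12),
                "tower": _DM((0, 0, 0), (0, 0, 1), -8),
                "wrist": _DM((0, 0.5, 0)),
            },
            dict(j),
            name="CTD toward fingers",
        ),
    ]


#: Stationary occupancies of the bundled ensembles.  Contact states carry a
#: combined mass of 0.40 (open-like) and 0.65 (closed-like), the fractions of
#: close-contact CTD-tower frames the corresponding real systems show;
#: occupancies are kept near-uniform so no basin is under-sampled.
OPENLIKE_PI = (0.20, 0.20, 0.20, 0.20, 0.20)
CLOSEDLIKE_PI = (0.16, 0.17, 0.18, 0.16, 0.17, 0.16)

_CONDITION_FAVOURED_OPEN = {"apo": 0, "DNA": 1, "ternary": 2, "RNA": 3}
_CONDITION_FAVOURED_CLOSED = {"RNA": 0, "ternary": 1, "DNA": 4, "apo": 5}


def _initial_distributions(favoured: Mapping[str, int], k: int) -> dict[str, np.ndarray]:
    dists = {}
    for condition, state in favoured.items():
        d = np.full(k, 0.5 / (k - 1))
        d[state] = 0.5
        dists[condition] = d
    return dists


def openlike_ensemble(
    frames_per_run: int = 150,
    runs_per_condition: int = 2,
    seed: int = 0,
    alpha: float = 0.7,
) -> EnsembleSpec:
    """Five-basin ensemble analogous to trajectories started from the open ring."""
    topology, dmap = default_topology()
    return EnsembleSpec(
        topology=topology,
        domain_map=dmap,
        states=_openlike_states(topology, dmap),
        transition=sticky_transition(OPENLIKE_PI, alpha),
        frames_per_run=frames_per_run,
        runs_per_condition={c: runs_per_condition for c in _CONDITION_FAVOURED_OPEN},
        initial_distribution=_initial_distributions(_CONDITION_FAVOURED_OPEN, 5),
        seed=seed,
        system_type="open",
    )


def closedlike_ensemble(
    frames_per_run: int = 150,
    runs_per_condition: int = 2,
    seed: int = 0,
    alpha: float = 0.7,
) -> EnsembleSpec:
    """Six-basin ensemble analogous to trajectories started from the closed ring."""
    topology, dmap = closed_topology()
    return EnsembleSpec(
        topology=topology,
        domain_map=dmap,
        states=_closedlike_states(topology, dmap),
        transition=sticky_transition(CLOSEDLIKE_PI, alpha),
        frames_per_run=frames_per_run,
        runs_per_condition={c: runs_per_condition for c in _CONDITION_FAVOURED_CLOSED},
        initial_distribution=_initial_distributions(_CONDITION_FAVOURED_CLOSED, 6),
        seed=seed,
        system_type="closed",
    )


def two_state_demo(
    frames_per_run: int = 200,
    runs_per_condition: int = 2,
    seed: int = 0,
    contact_occupancy: float = 0.4,
) -> EnsembleSpec:
    """Minimal two-basin ensemble (contact / no contact) for demos and tests."""
    topology, dmap = default_topology()
    u_c = contact_translation(topology, dmap)
    j = DEFAULT_JITTER
    states = [
        StateSpec({}, dict(j), name="apart"),
        StateSpec(
            {
                "CTD": _DM(tuple(u_c)),
                "EN": _DM((-12, 0, 6)),
            },
            dict(j),
            name="contact",
        ),
    ]
    pi = (1.0 - contact_occupancy, contact_occupancy)
    return EnsembleSpec(
        topology=topology,
        domain_map=dmap,
        states=states,
        transition=sticky_transition(pi, alpha=0.9),
        frames_per_run=frames_per_run,
        runs_per_condition={"apo": runs_per_condition},
        initial_distribution={"apo": np.asarray(pi)},
        seed=seed,
        system_type="custom",
    )


def three_mode_trajectory(
    n_frames: int = 400,
    seed: int = 0,
    amplitudes: tuple[float, float, float] = (6.0, 6.2, 7.0),
    jitter: float = 0.1,
) -> Trajectory:
    """Ensemble driven by exactly three dominant rigid translation modes.

    Frame t displaces the EN, CTD and tower domains along their "radial" axes
    (the directions that change interdomain distances most) with independent
    Gaussian amplitudes (standard deviations in A) plus small isotropic
    jitter, so the pairwise-distance feature matrix has three dominant
    principal components of comparable variance.  Used to check
    variance-threshold component selection.
    """
    topology, dmap = default_topology()
    rng = np.random.default_rng(seed)
    u_en, uhat_c = _motion_axes(topology, dmap)
    others = [d for d in dmap.names() if d != "tower"]
    rest = np.mean(
        [topology.coords[dmap.atom_indices(topology, d)].mean(axis=0) for d in others],
        axis=0,
    )
    tower = topology.coords[dmap.atom_indices(topology, "tower")].mean(axis=0)
    u_tw = (tower - rest) / np.linalg.norm(tower - rest)
    directions = {"EN": u_en, "CTD": -uhat_c, "tower": u_tw}
    coords = np.repeat(topology.coords[None], n_frames, axis=0)
    for (domain, direction), amp in zip(directions.items(), amplitudes):
        idx = dmap.atom_indices(topology, domain)
        coeffs = rng.normal(0.0, amp, size=n_frames)
        coords[:, idx, :] += coeffs[:, None, None] * direction[None, None, :]
    coords += rng.standard_normal(coords.shape) * jitter
    return Trajectory(topology, coords, run_id="modes-0", condition="modes")


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_run(
    trajectory: Trajectory,
    truth: GroundTruth,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write one run: multi-model PDB, ground-truth label CSV, spec YAML."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "trajectory": outdir / f"{trajectory.run_id}.pdb",
        "labels": outdir / f"{trajectory.run_id}_labels.csv",
        "spec": outdir / "ensemble_spec.yaml",
    }
    write_trajectory(trajectory, paths["trajectory"])
    pd.DataFrame(
        {"frame": np.arange(len(truth.labels)), "state": truth.labels}
    ).to_csv(paths["labels"], index=False)
    if truth.spec is not None and not paths["spec"].exists():
        truth.spec.to_yaml(paths["spec"])
    return paths
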