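"""Core structural data types, domain definitions and PDB/trajectory I/O.

Coordinates are always in Angstrom and residue numbering is 1-based with
inclusive intervals.  A :class:`Structure` is one conformation of a single
protein chain; a :class:`Trajectory` is an ordered stack of conformations
sharing that topology, tagged with run/condition metadata.  A
:class:`DomainMap` names residue intervals (e.g. the seven domains of a
retrotransposon-polymerase-like multidomain protein) and derives composite
selections such as the rigid fingers-palm-thumb (FPT) core used as the
alignment frame for all RMSD analyses.

PDB parsing and writing are delegated to :mod:`biotite`; DCD/XTC trajectory
coordinates are read through :mod:`mdtraj` when requested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

import biotite.structure as struc
import biotite.structure.io.pdb as pdbio

logger = logging.getLogger(__name__)

#: Default residue intervals (1-based, inclusive) of the seven-domain layout.
#: Residue 1061 is printed as belonging to both wrist and CTD; the overlap is
#: kept as-is and per-domain selections include shared residues in both.
DEFAULT_DOMAINS: dict[str, tuple[int, int]] = {
    "EN": (1, 238),
    "tower": (239, 439),
    "fingers": (440, 557),
    "palm": (558, 775),
    "thumb": (776, 862),
    "wrist": (863, 1061),
    "CTD": (1061, 1275),
}

#: Adjusted CTD/wrist intervals used for CTD-wrist minimum-distance analyses,
#: which exclude the trivial chain-contiguity contacts at the wrist/CTD seam.
ADJUSTED_CTD_WRIST: dict[str, tuple[int, int]] = {
    "CTD": (1068, 1275),
    "wrist": (877, 1056),
}


@dataclass(frozen=True)
class Atom:
    """A single atom: 1-based residue index, names, and coordinates in A."""

    residue_index: int
    residue_name: str
    atom_name: str
    coords: np.ndarray

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (3,):
            raise ValueError(f"coords must be a 3-vector, got shape {coords.shape}")
        if not np.all(np.isfinite(coords)):
            raise ValueError("atom coordinates must be finite")
        if self.residue_index < 1:
            raise ValueError(f"residue_index must be >= 1, got {self.residue_index}")
        object.__setattr__(self, "coords", coords)


class Structure:
    """One conformation of a protein chain.

    Atoms are stored in chain order as parallel arrays; ``atoms`` exposes them
    as :class:`Atom` objects.  Residue indices must be non-decreasing along
    the chain and each residue may carry at most one CA atom.
    """

    def __init__(
        self,
        residue_indices: Sequence[int],
        residue_names: Sequence[str],
        atom_names: Sequence[str],
        coords: np.ndarray,
        identifier: str = "",
    ):
        self.residue_indices = np.asarray(residue_indices, dtype=int)
        self.residue_names = np.asarray(residue_names, dtype="U5")
        self.atom_names = np.asarray(atom_names, dtype="U5")
        self.coords = np.asarray(coords, dtype=float)
        self.identifier = identifier
        self._validate()

    def _validate(self) -> None:
        n = len(self.residue_indices)
        if n == 0:
            raise ValueError("structure must contain at least one atom")
        if self.coords.shape != (n, 3):
            raise ValueError(
                f"coords shape {self.coords.shape} inconsistent with {n} atoms"
            )
        if len(self.residue_names) != n or len(self.atom_names) != n:
            raise ValueError("atom annotation arrays must have equal lengths")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if np.any(self.residue_indices < 1):
            raise ValueError("residue indices must be >= 1")
        if np.any(np.diff(self.residue_indices) < 0):
            raise ValueError("residue indices must be non-decreasing along the chain")
        ca_res = self.residue_indices[self.atom_names == "CA"]
        if len(np.unique(ca_res)) != len(ca_res):
            raise ValueError("at most one CA atom per residue index")

    # -- convenience -------------------------------------------------------

    @classmethod
    def from_atoms(cls, atoms: Sequence[Atom], identifier: str = "") -> "Structure":
        return cls(
            [a.residue_index for a in atoms],
            [a.residue_name for a in atoms],
            [a.atom_name for a in atoms],
            np.array([a.coords for a in atoms], dtype=float),
            identifier=identifier,
        )

    @property
    def atoms(self) -> list[Atom]:
        return [
            Atom(int(ri), rn, an, c)
            for ri, rn, an, c in zip(
                self.residue_indices, self.residue_names, self.atom_names, self.coords
            )
        ]

    @property
    def n_atoms(self) -> int:
        return len(self.residue_indices)

    def with_coords(self, coords: np.ndarray, identifier: str | None = None) -> "Structure":
        """Copy of this structure with replaced coordinates."""
        return Structure(
            self.residue_indices,
            self.residue_names,
            self.atom_names,
            coords,
            identifier=self.identifier if identifier is None else identifier,
        )

    def __eq__(self, other) -> bool:  # format-precision equality is the caller's job
        if not isinstance(other, Structure):
            return NotImplemented
        return (
            np.array_equal(self.residue_indices, other.residue_indices)
            and np.array_equal(self.residue_names, other.residue_names)
            and np.array_equal(self.atom_names, other.atom_names)
            and np.array_equal(self.coords, other.coords)
        )

    def __repr__(self) -> str:
        return f"<Structure {self.identifier!r}, {self.n_atoms} atoms>"


@dataclass
class Trajectory:
    """Ordered frames of coordinates over one topology, plus run metadata."""

    topology: Structure
    coords: np.ndarray  # (n_frames, n_atoms, 3), A
    run_id: str = ""
    condition: str = ""
    system_type: str = "custom"

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (frames, atoms, 3)")
        if self.coords.shape[0] < 1:
            raise ValueError("trajectory must contain at least one frame")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frame atom count {self.coords.shape[1]} does not match "
                f"topology ({self.topology.n_atoms} atoms)"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("trajectory coordinates must be finite")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame(self, i: int) -> Structure:
        return self.topology.with_coords(self.coords[i])


class DomainMap:
    """Named residue intervals, 1-based inclusive, with composite selections."""

    def __init__(self, intervals: Mapping[str, tuple[int, int]] | None = None):
        intervals = dict(DEFAULT_DOMAINS if intervals is None else intervals)
        for name, (start, end) in intervals.items():
            if start > end:
                raise ValueError(f"domain {name!r}: start {start} > end {end}")
            if start < 1:
                raise ValueError(f"domain {name!r}: residues are 1-based")
        if len(set(intervals)) != len(intervals):
            raise ValueError("domain names must be unique")
        self.intervals: dict[str, tuple[int, int]] = {
            k: (int(v[0]), int(v[1])) for k, v in intervals.items()
        }

    def __contains__(self, name: str) -> bool:
        return name in self.intervals

    def names(self) -> list[str]:
        return list(self.intervals)

    def interval(self, name: str) -> tuple[int, int]:
        return self.intervals[name]

    def intervals_for(self, name: str) -> list[tuple[int, int]]:
        """Intervals of a named domain, resolving composites like ``FPT``."""
        if name == "FPT" and "FPT" not in self.intervals:
            missing = [d for d in ("fingers", "palm", "thumb") if d not in self.intervals]
            if missing:
                raise KeyError(f"FPT composite needs fingers/palm/thumb; missing {missing}")
            return [self.intervals[d] for d in ("fingers", "palm", "thumb")]
        return [self.intervals[name]]

    def residues(self, name: str) -> np.ndarray:
        """All residue indices of a (possibly composite) domain."""
        return np.concatenate(
            [np.arange(s, e + 1) for s, e in self.intervals_for(name)]
        )

    def domains_of(self, residue_index: int) -> list[str]:
        """Domains containing a residue; raises if it falls outside all."""
        hits = [
            name
            for name, (s, e) in self.intervals.items()
            if s <= residue_index <= e
        ]
        if not hits:
            raise KeyError(f"residue {residue_index} is outside all domain intervals")
        return hits

    def atom_indices(
        self, structure: Structure, name: str, atom_name: str = "CA"
    ) -> np.ndarray:
        """Indices of atoms of ``atom_name`` within a named (composite) domain."""
        parts = [
            select_atoms(structure, atom_name, interval)
            for interval in self.intervals_for(name)
        ]
        idx = np.unique(np.concatenate(parts)) if parts else np.array([], dtype=int)
        return idx.astype(int)

    # -- config round trip -------------------------------------------------

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DomainMap":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls({str(k): (int(v[0]), int(v[1])) for k, v in raw.items()})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {k: [int(v[0]), int(v[1])] for k, v in self.intervals.items()}, fh
            )

    def __eq__(self, other) -> bool:
        if not isinstance(other, DomainMap):
            return NotImplemented
        return self.intervals == other.intervals

    def __repr__(self) -> str:
        return f"DomainMap({self.intervals!r})"


def adjusted_ctd_wrist_map(base: DomainMap | None = None) -> DomainMap:
    """Domain map preset with CTD 1068-1275 and wrist 877-1056.

    Used for CTD-wrist minimum-distance analyses, where the trivial contacts
    at the covalent wrist/CTD seam would otherwise dominate every frame.
    """
    base = DomainMap() if base is None else base
    intervals = dict(base.intervals)
    intervals.update(ADJUSTED_CTD_WRIST)
    return DomainMap(intervals)


# ---------------------------------------------------------------------------
# Atom selection
# ---------------------------------------------------------------------------

def select_atoms(
    structure: Structure,
    atom_name: str,
    residue_interval: tuple[int, int] | None = None,
) -> np.ndarray:
    """Strictly increasing indices of atoms matching name and residue interval."""
    mask = structure.atom_names == atom_name
    if residue_interval is not None:
        start, end = residue_interval
        if start > end:
            raise ValueError(f"invalid residue interval ({start}, {end})")
        mask &= (structure.residue_indices >= start) & (structure.residue_indices <= end)
    return np.flatnonzero(mask)


def backbone_indices(structure: Structure, residue_interval: tuple[int, int] | None = None) -> np.ndarray:
    """Backbone atom indices: N, CA, C where present; CA-only data yields CA."""
    parts = [select_atoms(structure, name, residue_interval) for name in ("N", "CA", "C")]
    return np.sort(np.concatenate(parts)).astype(int)


# ---------------------------------------------------------------------------
# PDB I/O (biotite backend)
# ---------------------------------------------------------------------------

def _first_chain(array):
    chains = np.unique(array.chain_id)
    if len(chains) > 1:
        logger.warning("multi-chain PDB: using first chain %r", chains[0])
        return array[array.chain_id == chains[0]]
    return array


def _to_structure(array, identifier: str) -> Structure:
    return Structure(
        array.res_id.astype(int),
        array.res_name,
        array.atom_name,
        np.asarray(array.coord, dtype=float),
        identifier=identifier,
    )


def _to_atom_array(structure: Structure):
    n = structure.n_atoms
    array = struc.AtomArray(n)
    array.chain_id = np.full(n, "A")
    array.res_id = structure.residue_indices
    array.res_name = structure.residue_names
    array.atom_name = structure.atom_names
    array.hetero = np.full(n, False)
    # element = leading letter of the atom name (good enough for N/C/O/S names)
    array.element = np.array(
        [next((c for c in name if c.isalpha()), "C") for name in structure.atom_names]
    )
    array.coord = np.asarray(structure.coords, dtype=float)
    return array


def read_pdb(path: str | Path, chain_id: str | None = None) -> Structure:
    """Read a single-model PDB file into a :class:`Structure`.

    Multi-model files raise; use :func:`read_trajectory` for those.  Only the
    first protein chain is used unless ``chain_id`` is given.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pdb_file = pdbio.PDBFile.read(str(path))
    n_models = pdb_file.get_model_count()
    if n_models == 0:
        raise ValueError(f"{path}: no ATOM records")
    if n_models > 1:
        raise ValueError(
            f"{path} contains {n_models} models; use read_trajectory() instead"
        )
    array = pdb_file.get_structure(model=1)
    if array.array_length() == 0:
        raise ValueError(f"{path}: no ATOM records")
    if chain_id is not None:
        array = array[array.chain_id == chain_id]
        if array.array_length() == 0:
            raise ValueError(f"{path}: no atoms with chain ID {chain_id!r}")
    else:
        array = _first_chain(array)
    return _to_structure(array, identifier=path.stem)


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a structure as a single-model PDB file."""
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(_to_atom_array(structure))
    pdb_file.write(str(path))


def read_trajectory(
    topology_path: str | Path,
    coord_path: str | Path | None = None,
    format: str | None = None,
    run_id: str = "",
    condition: str = "",
    system_type: str = "custom",
    chain_id: str | None = None,
) -> Trajectory:
    """Read a trajectory from a multi-model PDB, or DCD/XTC plus a topology.

    For multi-model PDB, ``topology_path`` is the trajectory itself (frame 1
    provides the topology) and ``coord_path`` may be omitted.  For DCD/XTC,
    ``topology_path`` is a single-model PDB and ``coord_path`` the coordinate
    file; those readers go through :mod:`mdtraj` (coordinates converted from
    nm to A).
    """
    topology_path = Path(topology_path)
    coord_path = topology_path if coord_path is None else Path(coord_path)
    if format is None:
        format = coord_path.suffix.lstrip(".").lower() or "pdb"
    format = format.lower()

    if format == "pdb":
        pdb_file = pdbio.PDBFile.read(str(coord_path))
        if pdb_file.get_model_count() == 0:
            raise ValueError(f"{coord_path}: no ATOM records")
        stack = pdb_file.get_structure()  # AtomArrayStack
        first = stack[0]
        if chain_id is not None:
            keep = first.chain_id == chain_id
        else:
            chains = np.unique(first.chain_id)
            keep = first.chain_id == chains[0]
        stack = stack[:, keep]
        topology = _to_structure(stack[0], identifier=topology_path.stem)
        coords = np.asarray(stack.coord, dtype=float)
        if coords.ndim == 2:
            coords = coords[None]
    elif format in ("dcd", "xtc"):
        import mdtraj

        mdt = mdtraj.load(str(coord_path), top=str(topology_path))
        topology = read_pdb(topology_path, chain_id=chain_id)
        coords = np.asarray(mdt.xyz, dtype=float) * 10.0  # nm -> A
        if coords.shape[1] != topology.n_atoms:
            raise ValueError(
                f"coordinate file has {coords.shape[1]} atoms but topology "
                f"has {topology.n_atoms}"
            )
    else:
        raise ValueError(f"unsupported trajectory format: {format!r}")

    return Trajectory(
        topology=topology,
        coords=coords,
        run_id=run_id or topology_path.stem,
        condition=condition,
        system_type=system_type,
    )


def write_trajectory(trajectory: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB file."""
    template = _to_atom_array(trajectory.topology)
    stack = struc.AtomArrayStack(trajectory.n_frames, template.array_length())
    for category in template.get_annotation_categories():
        stack.set_annotation(category, template.get_annotation(category))
    stack.coord = np.asarray(trajectory.coords, dtype=float)
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))
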