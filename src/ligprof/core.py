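"""Core domain types for structural-ensemble profiling.

The data model is deliberately small: a :class:`Topology` of immutable
:class:`AtomRecord` entries, an :class:`Ensemble` holding ``T`` frames of
Cartesian coordinates over that fixed topology, a :class:`LigandSpec`
naming which residues form a ligand and which atom names form its polar
"headgroup", and a :class:`DensityMap` regular-grid container.

Conventions
-----------
* Coordinates are in Ångström, right-handed, exactly as stored.  No
  periodic-boundary imaging is performed; inputs must be pre-imaged.
  :meth:`Ensemble.check_bounding_box` flags frames whose bounding-box
  diagonal exceeds a configurable limit as a cheap sanity check.
* Residue numbering is taken verbatim from the input (1-based PDB
  convention); frames are 0-indexed and frame 0 is the reference
  ("initial") configuration.
* Hydrogens are retained in the data model but excluded by default from
  every distance and density analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ATOM_CATEGORIES",
    "ELEMENT_MASSES",
    "STANDARD_AMINO_ACIDS",
    "DEFAULT_WATER_RESNAMES",
    "BACKBONE_ATOM_NAMES",
    "AtomRecord",
    "Topology",
    "Ensemble",
    "LigandSpec",
    "DensityMap",
    "ClassifyRules",
    "ResidueKey",
    "EnsembleFormatError",
    "DensityFormatError",
    "ConfigurationError",
    "SelectionError",
    "DegenerateGeometryError",
]

ATOM_CATEGORIES = (
    "protein_backbone",
    "protein_sidechain",
    "ligand",
    "water",
    "other",
)

#: Standard atomic masses (u) for the elements that occur in biomolecular
#: systems.  PDB occupancy/B-factor columns are ignored; masses always come
#: from this table (or an explicit override on the record).
ELEMENT_MASSES: dict[str, float] = {
    "H": 1.008,
    "D": 2.014,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "NA": 22.990,
    "MG": 24.305,
    "P": 30.974,
    "S": 32.06,
    "CL": 35.45,
    "K": 39.098,
    "CA": 40.078,
    "MN": 54.938,
    "FE": 55.845,
    "ZN": 65.38,
    "BR": 79.904,
    "I": 126.904,
}

STANDARD_AMINO_ACIDS = frozenset(
    """ALA ARG ASN ASP CYS GLN GLU GLY HIS HID HIE HIP HSD HSE HSP ILE LEU
    LYS MET PHE PRO SER THR TRP TYR VAL""".split()
)

DEFAULT_WATER_RESNAMES = frozenset({"HOH", "WAT", "TIP3", "SOL"})

#: Protein backbone heavy-atom names; everything else in a protein residue
#: is sidechain (glycine therefore has no sidechain heavy atoms and can
#: never register a sidechain contact).
BACKBONE_ATOM_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})

#: A residue is identified throughout the package by (residue_seq,
#: residue_name); the subunit (chain) is carried separately because the
#: same residue exists once per symmetry-related subunit.
ResidueKey = tuple[int, str]


class EnsembleFormatError(ValueError):
    """A structural-ensemble file violates its dialect contract."""


class DensityFormatError(ValueError):
    """A volumetric grid file could not be parsed."""


class ConfigurationError(ValueError):
    """Inconsistent analysis parameters (e.g. mismatched profiles)."""


class SelectionError(ValueError):
    """An atom/residue selection resolved to nothing usable."""


class DegenerateGeometryError(ValueError):
    """Geometry too degenerate for the requested operation."""


@dataclass(frozen=True)
class AtomRecord:
    """Static metadata for a single atom.

    Parameters
    ----------
    atom_id : int
        Unique serial number, ``>= 1``.
    atom_name : str
        PDB-style atom name (``CA``, ``OE1`` ...).
    element : str
        Element symbol, upper case.
    mass : float
        Atomic mass in u; must be positive.
    residue_seq : int
        Residue sequence number as given by the input.
    residue_name : str
        Three-letter residue name.
    subunit_id : str
        Chain identifier.
    category : str
        One of :data:`ATOM_CATEGORIES`.
    """

    atom_id: int
    atom_name: str
    element: str
    mass: float
    residue_seq: int
    residue_name: str
    subunit_id: str
    category: str

    def __post_init__(self) -> None:
        if self.atom_id < 1:
            raise ValueError(f"atom_id must be >= 1, got {self.atom_id}")
        if not self.element:
            raise ValueError("element must be nonempty")
        if self.mass <= 0:
            raise ValueError(f"mass must be positive, got {self.mass}")
        if self.category not in ATOM_CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")

    @property
    def residue_key(self) -> ResidueKey:
        return (self.residue_seq, self.residue_name)


@dataclass(frozen=True)
class ClassifyRules:
    """Rules assigning each atom to exactly one category.

    An atom in a water residue (by name) is ``water``; in a recognised
    protein residue it is ``protein_backbone`` if its name is in
    ``backbone_atom_names`` else ``protein_sidechain``; in a declared
    ligand residue it is ``ligand``; anything else is ``other`` (with a
    warning, so typos in ligand residue names surface early).
    """

    water_resnames: frozenset[str] = DEFAULT_WATER_RESNAMES
    protein_resnames: frozenset[str] = STANDARD_AMINO_ACIDS
    backbone_atom_names: frozenset[str] = BACKBONE_ATOM_NAMES
    ligand_resnames: frozenset[str] = frozenset()
    warn_unknown: bool = True

    def category(self, residue_name: str, atom_name: str) -> str:
        rn = residue_name.upper()
        if rn in self.water_resnames:
            return "water"
        if rn in self.protein_resnames:
            if atom_name.upper() in self.backbone_atom_names:
                return "protein_backbone"
            return "protein_sidechain"
        if rn in self.ligand_resnames:
            return "ligand"
        if self.warn_unknown:
            warnings.warn(
                f"residue name {residue_name!r} not recognised; "
                "atoms assigned category 'other'",
                stacklevel=3,
            )
        return "other"


class Topology:
    """Ordered, immutable collection of :class:`AtomRecord`.

    The atom order is fixed for the life of any ensemble built on top of
    it.  Cached NumPy views of the per-atom annotations support fast
    selections without touching the Python records.
    """

    def __init__(self, atoms: Sequence[AtomRecord]):
        atoms = tuple(atoms)
        if not atoms:
            raise ValueError("topology needs at least one atom")
        ids = [a.atom_id for a in atoms]
        if len(set(ids)) != len(ids):
            raise ValueError("atom_id values must be unique")
        # each (subunit, residue_seq) must map to exactly one residue name
        seen: dict[tuple[str, int], str] = {}
        for a in atoms:
            key = (a.subunit_id, a.residue_seq)
            prev = seen.setdefault(key, a.residue_name)
            if prev != a.residue_name:
                raise ValueError(
                    f"residue {key} has conflicting names {prev!r} and "
                    f"{a.residue_name!r}"
                )
        self._atoms = atoms
        self.atom_name = np.array([a.atom_name for a in atoms])
        self.element = np.array([a.element.upper() for a in atoms])
        self.mass = np.array([a.mass for a in atoms], dtype=float)
        self.residue_seq = np.array([a.residue_seq for a in atoms], dtype=int)
        self.residue_name = np.array([a.residue_name for a in atoms])
        self.subunit = np.array([a.subunit_id for a in atoms])
        self.category = np.array([a.category for a in atoms])
        self.is_hydrogen = np.isin(self.element, ("H", "D"))
        # ordered distinct subunit ids (order of first appearance)
        _, first = np.unique(self.subunit, return_index=True)
        self.subunit_ids: tuple[str, ...] = tuple(
            self.subunit[i] for i in sorted(first)
        )

    @property
    def atoms(self) -> tuple[AtomRecord, ...]:
        return self._atoms

    @property
    def n_atoms(self) -> int:
        return len(self._atoms)

    def __len__(self) -> int:
        return self.n_atoms

    def select(
        self,
        *,
        subunit: str | None = None,
        residue_seq: int | Iterable[int] | None = None,
        residue_name: str | None = None,
        category: str | Iterable[str] | None = None,
        atom_name: Iterable[str] | None = None,
        element: Iterable[str] | None = None,
        heavy_only: bool = False,
    ) -> np.ndarray:
        """Indices of atoms matching every given criterion."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if subunit is not None:
            mask &= self.subunit == subunit
        if residue_seq is not None:
            seqs = (
                [residue_seq] if np.isscalar(residue_seq) else list(residue_seq)
            )
            mask &= np.isin(self.residue_seq, seqs)
        if residue_name is not None:
            mask &= self.residue_name == residue_name
        if category is not None:
            cats = [category] if isinstance(category, str) else list(category)
            mask &= np.isin(self.category, cats)
        if atom_name is not None:
            mask &= np.isin(self.atom_name, list(atom_name))
        if element is not None:
            mask &= np.isin(self.element, [e.upper() for e in element])
        if heavy_only:
            mask &= ~self.is_hydrogen
        return np.flatnonzero(mask)

    def residue_keys(
        self, subunit: str | None = None, category: Iterable[str] | None = None
    ) -> list[ResidueKey]:
        """Distinct (residue_seq, residue_name) keys, in sequence order."""
        idx = self.select(subunit=subunit, category=category)
        pairs = {
            (int(s), str(n))
            for s, n in zip(self.residue_seq[idx], self.residue_name[idx])
        }
        return sorted(pairs)


@dataclass
class Ensemble:
    """``T`` frames of N x 3 coordinates (Å) over a fixed topology.

    Frame 0 is the reference ("initial") configuration for every analysis
    that needs one.
    """

    topology: Topology
    coords: np.ndarray  # (T, N, 3) float64, Å

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(
                f"coords must be (T, N, 3); got {self.coords.shape}"
            )
        if self.coords.shape[0] < 1:
            raise ValueError("ensemble needs at least one frame")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"coords have {self.coords.shape[1]} atoms but topology has "
                f"{self.topology.n_atoms}"
            )
        if not np.isfinite(self.coords).all():
            raise ValueError("coordinates must be finite")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def check_bounding_box(self, max_diagonal: float = 1000.0) -> list[int]:
        """Frames whose bounding-box diagonal exceeds ``max_diagonal`` Å.

        Inputs are required to be pre-imaged (no periodic wrapping is ever
        applied); a huge bounding box is the usual symptom of an un-imaged
        trajectory and is worth flagging before any distance analysis.
        """
        span = self.coords.max(axis=1) - self.coords.min(axis=1)
        diag = np.linalg.norm(span, axis=1)
        return [int(i) for i in np.flatnonzero(diag > max_diagonal)]


@dataclass(frozen=True)
class LigandSpec:
    """Which residues form a ligand and which atoms form its headgroup.

    The "headgroup" is the polar substructure (for a phosphoinositide the
    inositol-phosphate moiety) against which contacts and minimum
    distances are measured.  Headgroup membership must be given by atom
    name; there is no chemical perception here.
    """

    label: str
    residues: frozenset[tuple[str, int]]  # (subunit_id, residue_seq)
    headgroup_atom_names: frozenset[str]

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("ligand needs at least one residue")
        if not self.headgroup_atom_names:
            raise ValueError("headgroup atom-name set must be nonempty")

    @property
    def subunits(self) -> tuple[str, ...]:
        return tuple(sorted({s for s, _ in self.residues}))

    def ligand_indices(
        self, topology: Topology, subunit: str, heavy_only: bool = True
    ) -> np.ndarray:
        """All atoms of this ligand's residues on ``subunit``."""
        seqs = [seq for su, seq in self.residues if su == subunit]
        if not seqs:
            return np.array([], dtype=int)
        return topology.select(
            subunit=subunit, residue_seq=seqs, heavy_only=heavy_only
        )

    def headgroup_indices(
        self, topology: Topology, subunit: str
    ) -> np.ndarray:
        """Heavy headgroup atoms of this ligand on ``subunit``."""
        idx = self.ligand_indices(topology, subunit, heavy_only=True)
        keep = np.isin(
            topology.atom_name[idx], list(self.headgroup_atom_names)
        )
        return idx[keep]

    def validate(self, topology: Topology) -> None:
        """Require >= 1 heavy headgroup atom for every selected residue."""
        for subunit, seq in sorted(self.residues):
            idx = topology.select(
                subunit=subunit, residue_seq=seq, heavy_only=True,
                atom_name=list(self.headgroup_atom_names),
            )
            if idx.size == 0:
                raise SelectionError(
                    f"ligand {self.label!r}: residue ({subunit}, {seq}) has "
                    "no heavy headgroup atom"
                )


@dataclass
class DensityMap:
    """Regular 3D grid of frame-averaged weighted atomic density.

    The voxel centre of index ``(i, j, k)`` (0-based) sits at
    ``origin + spacing * (i, j, k)``.  ``weight_mode`` records whether
    values are mass-weighted (u/Å^3) or occupancy counts (1/Å^3).
    """

    origin: np.ndarray  # (3,) Å
    spacing: float  # Å, uniform
    values: np.ndarray  # (nx, ny, nz), >= 0
    weight_mode: str = "mass"
    n_frames_averaged: int = 1

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array")
        if self.spacing <= 0:
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if self.weight_mode not in ("mass", "occupancy"):
            raise ValueError(f"unknown weight_mode {self.weight_mode!r}")
        if self.n_frames_averaged < 1:
            raise ValueError("n_frames_averaged must be >= 1")
        if not np.isfinite(self.values).all():
            raise ValueError("map values must be finite")
        if (self.values < 0).any():
            raise ValueError("map values must be nonnegative")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        return float(self.spacing) ** 3

    def integral(self) -> float:
        """Discrete integral: sum of values times voxel volume."""
        return float(self.values.sum() * self.voxel_volume)

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-centre coordinates along each axis."""
        return tuple(
            self.origin[d] + self.spacing * np.arange(self.dims[d])
            for d in range(3)
        )  # type: ignore[return-value]


def mass_for_element(element: str) -> float:
    """Mass (u) from the built-in element table; raises on unknowns."""
    try:
        return ELEMENT_MASSES[element.upper()]
    except KeyError:
        raise KeyError(
            f"no mass for element {element!r}; extend ELEMENT_MASSES or "
            "supply masses explicitly"
        ) from None
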