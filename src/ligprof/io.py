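"""Readers and writers for structural ensembles, ligand specs and maps.

Two ensemble dialects are supported:

``pdb_multimodel``
    Multi-model PDB (``MODEL``/``ENDMDL`` blocks), parsed with biotite.
    All models must contain the same atoms in the same order.
``frame_table``
    Whitespace-separated ``frame atom_id x y z`` rows plus a sidecar
    topology table (TSV with columns ``atom_id atom_name element
    residue_seq residue_name subunit_id``).

Density maps use the OpenDX scalar-grid format via gridDataFormats.
Binary trajectory formats (DCD/XTC) are out of scope; convert externally.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio
from gridData import Grid

from .core import (
    AtomRecord,
    ClassifyRules,
    DensityFormatError,
    DensityMap,
    Ensemble,
    EnsembleFormatError,
    LigandSpec,
    Topology,
    mass_for_element,
)

__all__ = [
    "read_structure_ensemble",
    "write_structure_ensemble",
    "read_density_map",
    "write_density_map",
    "read_ligand_spec",
    "write_ligand_spec",
]


def _scan_pdb_model_counts(path: Path) -> list[int]:
    """Atom counts per MODEL block (cheap pre-scan for clear errors)."""
    counts: list[int] = []
    current: int | None = None
    with open(path) as fh:
        for line in fh:
            rec = line[:6]
            if rec == "MODEL ":
                current = 0
            elif rec in ("ATOM  ", "HETATM"):
                if current is None:  # single-model file without MODEL card
                    current = 0
                current += 1
            elif rec == "ENDMDL":
                counts.append(current or 0)
                current = None
    if current is not None and current > 0:  # no trailing ENDMDL
        counts.append(current)
    return counts


def _element_from_name(atom_name: str) -> str:
    """Fallback element guess when the PDB element column is blank."""
    stripped = atom_name.strip().lstrip("0123456789")
    if stripped[:2].upper() in ("CL", "BR", "NA", "MG", "ZN", "FE", "MN"):
        return stripped[:2].upper()
    return stripped[:1].upper()


def _topology_from_arrays(
    atom_name: np.ndarray,
    element: np.ndarray,
    residue_seq: np.ndarray,
    residue_name: np.ndarray,
    subunit: np.ndarray,
    rules: ClassifyRules,
) -> Topology:
    records = []
    for i in range(len(atom_name)):
        elem = str(element[i]).upper() or _element_from_name(str(atom_name[i]))
        records.append(
            AtomRecord(
                atom_id=i + 1,
                atom_name=str(atom_name[i]),
                element=elem,
                mass=mass_for_element(elem),
                residue_seq=int(residue_seq[i]),
                residue_name=str(residue_name[i]),
                subunit_id=str(subunit[i]),
                category=rules.category(str(residue_name[i]), str(atom_name[i])),
            )
        )
    return Topology(records)


def _read_pdb_multimodel(path: Path, rules: ClassifyRules) -> Ensemble:
    counts = _scan_pdb_model_counts(path)
    if not counts:
        raise EnsembleFormatError(f"{path}: no atoms found")
    for i, c in enumerate(counts[1:], start=2):
        if c != counts[0]:
            raise EnsembleFormatError(
                f"model {i}: {c} atoms, expected {counts[0]}"
            )
    pdb_file = pdbio.PDBFile.read(str(path))
    stack = pdb_file.get_structure(model=None)
    if isinstance(stack, struc.AtomArray):  # pragma: no cover - defensive
        stack = struc.stack([stack])
    first = stack[0]
    topology = _topology_from_arrays(
        first.atom_name,
        first.element,
        first.res_id,
        first.res_name,
        first.chain_id,
        rules,
    )
    return Ensemble(topology, np.asarray(stack.coord, dtype=float))


_TOPOLOGY_COLUMNS = [
    "atom_id",
    "atom_name",
    "element",
    "residue_seq",
    "residue_name",
    "subunit_id",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".topology.tsv")


def _read_frame_table(
    path: Path, rules: ClassifyRules, topology_path: Path | None
) -> Ensemble:
    topo_path = topology_path or _sidecar_path(path)
    if not topo_path.exists():
        raise EnsembleFormatError(
            f"frame_table dialect needs a sidecar topology file; "
            f"{topo_path} not found"
        )
    topo_df = pd.read_csv(topo_path, sep="\t")
    missing = set(_TOPOLOGY_COLUMNS) - set(topo_df.columns)
    if missing:
        raise EnsembleFormatError(
            f"{topo_path}: missing topology columns {sorted(missing)}"
        )
    topo_df = topo_df.sort_values("atom_id")
    topology = _topology_from_arrays(
        topo_df["atom_name"].to_numpy(dtype=str),
        topo_df["element"].to_numpy(dtype=str),
        topo_df["residue_seq"].to_numpy(),
        topo_df["residue_name"].to_numpy(dtype=str),
        topo_df["subunit_id"].to_numpy(dtype=str),
        rules,
    )
    table = pd.read_csv(
        path,
        sep=r"\s+",
        comment="#",
        names=["frame", "atom_id", "x", "y", "z"],
        header=None,
    )
    n = topology.n_atoms
    frames = sorted(table["frame"].unique())
    if frames != list(range(len(frames))):
        raise EnsembleFormatError(
            f"{path}: frame indices must be contiguous from 0"
        )
    order = {int(a.atom_id): i for i, a in enumerate(topology.atoms)}
    coords = np.full((len(frames), n, 3), np.nan)
    for t, grp in table.groupby("frame"):
        if len(grp) != n:
            raise EnsembleFormatError(
                f"model {int(t) + 1}: {len(grp)} atoms, expected {n}"
            )
        rows = [order[int(a)] for a in grp["atom_id"]]
        coords[int(t), rows] = grp[["x", "y", "z"]].to_numpy()
    return Ensemble(topology, coords)


def read_structure_ensemble(
    path: str | os.PathLike,
    dialect: str = "pdb_multimodel",
    classify_rules: ClassifyRules | None = None,
    topology_path: str | os.PathLike | None = None,
) -> Ensemble:
    """Read a multi-frame ensemble from disk.

    Parameters
    ----------
    path
        Input file.
    dialect
        ``pdb_multimodel`` or ``frame_table``.
    classify_rules
        Category-assignment rules; defaults to :class:`ClassifyRules`.
    topology_path
        Sidecar topology table for ``frame_table`` (defaults to
        ``<path>.topology.tsv``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rules = classify_rules or ClassifyRules()
    if dialect == "pdb_multimodel":
        return _read_pdb_multimodel(path, rules)
    if dialect == "frame_table":
        return _read_frame_table(
            path, rules, Path(topology_path) if topology_path else None
        )
    raise ValueError(f"unknown ensemble dialect {dialect!r}")


def write_structure_ensemble(
    ensemble: Ensemble,
    path: str | os.PathLike,
    dialect: str = "pdb_multimodel",
) -> None:
    """Write an ensemble in one of the supported dialects.

    PDB output stores coordinates at fixed-width precision (1e-3 Å), so a
    write/read round-trip reproduces coordinates to that tolerance only.
    """
    path = Path(path)
    topo = ensemble.topology
    if dialect == "pdb_multimodel":
        n = topo.n_atoms
        stack = struc.AtomArrayStack(ensemble.n_frames, n)
        stack.coord = ensemble.coords.astype(np.float32)
        stack.chain_id = topo.subunit
        stack.res_id = topo.residue_seq
        stack.res_name = topo.residue_name
        stack.atom_name = topo.atom_name
        stack.element = topo.element
        stack.hetero = ~np.isin(
            topo.category, ("protein_backbone", "protein_sidechain")
        )
        pdb_file = pdbio.PDBFile()
        pdb_file.set_structure(stack)
        pdb_file.write(str(path))
    elif dialect == "frame_table":
        topo_df = pd.DataFrame(
            {
                "atom_id": [a.atom_id for a in topo.atoms],
                "atom_name": topo.atom_name,
                "element": topo.element,
                "residue_seq": topo.residue_seq,
                "residue_name": topo.residue_name,
                "subunit_id": topo.subunit,
            }
        )
        topo_df.to_csv(_sidecar_path(path), sep="\t", index=False)
        with open(path, "w") as fh:
            fh.write("# frame atom_id x y z\n")
            ids = [a.atom_id for a in topo.atoms]
            for t in range(ensemble.n_frames):
                for i, aid in enumerate(ids):
                    x, y, z = ensemble.coords[t, i]
                    fh.write(f"{t} {aid} {x:.6f} {y:.6f} {z:.6f}\n")
    else:
        raise ValueError(f"unknown ensemble dialect {dialect!r}")


def write_density_map(density_map: DensityMap, path: str | os.PathLike) -> None:
    """Write a :class:`DensityMap` as an OpenDX scalar grid."""
    grid = Grid(
        density_map.values,
        origin=density_map.origin,
        delta=density_map.spacing,
    )
    grid.export(str(path), file_format="dx")


def read_density_map(
    path: str | os.PathLike, weight_mode: str = "occupancy"
) -> DensityMap:
    """Read an OpenDX scalar grid.

    ``weight_mode`` defaults to ``occupancy`` because DX files carry no
    weighting annotation; pass ``mass`` if the file is known to be a
    mass-weighted map.  Non-uniform grid spacing is rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        grid = Grid(str(path))
    except Exception as exc:
        raise DensityFormatError(
            f"{path}: not a readable OpenDX grid "
            f"(first problem near line {_first_bad_dx_line(path)}): {exc}"
        ) from exc
    delta = np.atleast_1d(np.asarray(grid.delta, dtype=float))
    if delta.ndim == 2:
        if not np.allclose(delta, np.diag(np.diagonal(delta))):
            raise DensityFormatError(f"{path}: non-orthogonal grid deltas")
        delta = np.diagonal(delta)
    if delta.size == 1:
        delta = np.repeat(delta, 3)
    if not np.allclose(delta, delta[0], rtol=1e-6):
        raise DensityFormatError(
            f"{path}: non-uniform grid spacing {delta} is unsupported"
        )
    return DensityMap(
        origin=np.asarray(grid.origin, dtype=float),
        spacing=float(delta[0]),
        values=np.asarray(grid.grid, dtype=float),
        weight_mode=weight_mode,
    )


def _first_bad_dx_line(path: Path) -> int:
    """Best-effort line number of the first structurally odd DX line."""
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#") or s.startswith("object"):
                continue
            if s.startswith(("origin", "delta", "attribute", "component")):
                continue
            try:
                [float(tok) for tok in s.split()]
            except ValueError:
                return i
    return i if "i" in locals() else 0


def write_ligand_spec(spec: LigandSpec, path: str | os.PathLike) -> None:
    """Write a ligand definition as YAML."""
    payload = {
        "label": spec.label,
        "headgroup_atoms": sorted(spec.headgroup_atom_names),
        "residues": [[s, int(r)] for s, r in sorted(spec.residues)],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def read_ligand_spec(path: str | os.PathLike) -> LigandSpec:
    """Read a YAML ligand definition written by :func:`write_ligand_spec`."""
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    try:
        return LigandSpec(
            label=str(payload["label"]),
            residues=frozenset(
                (str(s), int(r)) for s, r in payload["residues"]
            ),
            headgroup_atom_names=frozenset(payload["headgroup_atoms"]),
        )
    except (KeyError, TypeError) as exc:
        raise EnsembleFormatError(
            f"{path}: invalid ligand spec ({exc})"
        ) from exc
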