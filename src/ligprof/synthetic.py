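"""Seeded generator of C4-symmetric tetramer+ligand ensembles.

The generator stands in for molecular-dynamics trajectories of a
homotetrameric channel with one phosphoinositide-like ligand bound per
subunit.  Its geometry is deliberately schematic — each residue is a
4-atom backbone proxy plus a 3-atom sidechain proxy, the ligand a small
headgroup triad plus an apolar tail — because the analyses under test
are purely geometric and need *known ground truth*, not realism.

Designed behaviours, all independent per frame and subunit:

* every residue carries, per ligand species, a designed contact
  probability ``p``: with probability ``p`` its sidechain is placed so
  that its minimum heavy-atom distance to the (jittered) ligand
  headgroup falls inside the 5 Å contact shell, otherwise well outside
  it, so empirical contact frequencies are exact Bernoulli(p) samples;
* selected residues instead get a designed mean separation (Gaussian
  around a target minimum distance), emulating near/far probe residues;
* ligand atoms are jittered with a per-species, per-coordinate Gaussian
  σ ("stable" vs "unstable" pose; frame 0 is the clean reference);
* one bridge water per subunit toggles between a bridging position
  (within hydrogen-bond distance of both a glutamine-like sidechain
  oxygen and a headgroup oxygen) and a remote position, with a designed
  occupancy.

A single seed drives everything through per-(species, frame, subunit)
PRNG substreams, so output is reproducible independent of loop order.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import norm

from .core import (
    AtomRecord,
    ClassifyRules,
    Ensemble,
    LigandSpec,
    ResidueKey,
    Topology,
    mass_for_element,
)
from .io import write_ligand_spec, write_structure_ensemble

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate_ensemble",
    "generate_study",
    "write_fixture",
    "ligand_spec_for",
    "fixture_classify_rules",
    "HEADGROUP_ATOM_NAMES",
]

HEADGROUP_ATOM_NAMES = frozenset({"P1", "O1", "O2"})
LIGAND_RESIDUE_SEQ = 900
WATER_RESIDUE_SEQ = 1000
FIRST_RESIDUE_SEQ = 501
CONTACT_SHELL = 5.0  # Å; the design margin brackets this cutoff

_AA_CYCLE = [
    "LEU", "ILE", "VAL", "PHE", "MET", "SER", "THR", "ALA", "TYR",
    "TRP", "GLU", "ASP", "LYS", "ARG", "ASN", "HIS", "PRO", "CYS",
]
_CHAINS = "ABCDEFGH"


def _default_contact_design() -> dict[int, dict[str, float]]:
    """The two-species study design.

    Eight residues contact species A persistently but species B rarely
    (the selective set), six contact both (the shared set), two prefer B,
    and everything else sits at the background rate.  Residue numbering
    starts at ``FIRST_RESIDUE_SEQ``.
    """
    design: dict[int, dict[str, float]] = {}
    for i in range(8):  # selective for species A
        design[FIRST_RESIDUE_SEQ + i] = {"PI": 0.9, "PIP2": 0.1}
    for i in range(8, 14):  # shared
        design[FIRST_RESIDUE_SEQ + i] = {"PI": 0.9, "PIP2": 0.9}
    for i in range(14, 16):  # selective for species B
        design[FIRST_RESIDUE_SEQ + i] = {"PI": 0.1, "PIP2": 0.9}
    return design


def _default_separation_design() -> dict[int, tuple[float, float]]:
    """Two probe residues with designed mean minimum distances (Å)."""
    return {
        FIRST_RESIDUE_SEQ + 16: (3.0, 0.3),
        FIRST_RESIDUE_SEQ + 17: (8.0, 0.3),
    }


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study; defaults are the study design.

    The default values encode the two-condition contrast the analyses
    are exercised on: a "stable" species PI (pose jitter σ = 0.5 Å) and
    an "unstable" species PIP2 (σ = 2.0 Å), designed selective/shared
    contact sets at p = 0.9 against a 0.1 background, two distance-probe
    residues at 3 Å and 8 Å, and a 0.7-occupancy water bridge at a
    glutamine-like residue.
    """

    n_frames: int = 1000
    seed: int = 42
    n_subunits: int = 4
    residues_per_subunit: int = 24
    ligands: tuple[str, ...] = ("PI", "PIP2")
    contact_design: dict[int, dict[str, float]] = field(
        default_factory=_default_contact_design
    )
    default_contact_p: float = 0.1
    separation_design: dict[int, tuple[float, float]] = field(
        default_factory=_default_separation_design
    )
    ligand_sigma: dict[str, float] = field(
        default_factory=lambda: {"PI": 0.5, "PIP2": 2.0}
    )
    protein_sigma: float = 0.05
    bridge_residue_seq: int | None = FIRST_RESIDUE_SEQ + 18
    bridge_occupancy: float = 0.7
    ligand_tail_atoms: int = 9
    #: distance draw (Å) when a designed contact is "in" the shell
    contact_d_in: tuple[float, float] = (2.8, 4.2)
    #: distance draw (Å) when it is "out"
    contact_d_out: tuple[float, float] = (6.8, 10.0)

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not 1 <= self.n_subunits <= len(_CHAINS):
            raise ValueError(f"n_subunits must be in 1..{len(_CHAINS)}")
        if self.residues_per_subunit < 3:
            raise ValueError("need at least 3 residues per subunit")
        for seq, per_ligand in self.contact_design.items():
            for label, p in per_ligand.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(
                        f"contact probability for residue {seq}/{label} "
                        f"out of [0,1]: {p}"
                    )
        if not 0.0 <= self.default_contact_p <= 1.0:
            raise ValueError("default_contact_p out of [0,1]")
        if not 0.0 <= self.bridge_occupancy <= 1.0:
            raise ValueError("bridge_occupancy out of [0,1]")
        for label in self.ligands:
            if self.ligand_sigma.get(label, 0.0) < 0:
                raise ValueError(f"ligand sigma for {label!r} must be >= 0")
        if self.protein_sigma < 0:
            raise ValueError("protein_sigma must be >= 0")
        if (
            self.bridge_residue_seq is not None
            and self.bridge_residue_seq not in self.residue_seqs()
        ):
            raise ValueError(
                f"bridge_residue_seq {self.bridge_residue_seq} outside the "
                f"modelled range {FIRST_RESIDUE_SEQ}.."
                f"{FIRST_RESIDUE_SEQ + self.residues_per_subunit - 1}"
            )

    def residue_seqs(self) -> list[int]:
        return [
            FIRST_RESIDUE_SEQ + i for i in range(self.residues_per_subunit)
        ]

    def residue_name(self, seq: int) -> str:
        if seq == self.bridge_residue_seq:
            return "GLN"
        return _AA_CYCLE[(seq - FIRST_RESIDUE_SEQ) % len(_AA_CYCLE)]

    def residue_key(self, seq: int) -> ResidueKey:
        return (seq, self.residue_name(seq))

    def contact_probability(self, seq: int, label: str) -> float:
        """Effective designed contact probability of a residue."""
        if seq == self.bridge_residue_seq:
            return 1.0  # the bridge residue is pinned inside the shell
        if seq in self.separation_design:
            mean, sd = self.separation_design[seq]
            return float(norm.cdf((CONTACT_SHELL - mean) / sd))
        return self.contact_design.get(seq, {}).get(
            label, self.default_contact_p
        )


@dataclass
class GroundTruth:
    """Designed quantities every analysis stage must recover."""

    contact_probabilities: dict[str, dict[ResidueKey, float]]
    ligand_sigma: dict[str, float]
    bridge_residue: ResidueKey | None
    bridge_occupancy: float
    mean_separations: dict[ResidueKey, float]
    selectivity_threshold: float = 0.5

    def classes(
        self, label_a: str, label_b: str, threshold: float | None = None
    ) -> dict[str, list[ResidueKey]]:
        """Designed selective/shared/neither partition at a threshold."""
        thr = self.selectivity_threshold if threshold is None else threshold
        pa = self.contact_probabilities[label_a]
        pb = self.contact_probabilities[label_b]
        out: dict[str, list[ResidueKey]] = {
            "selective_a": [],
            "selective_b": [],
            "shared": [],
            "neither": [],
        }
        for key in sorted(pa):
            a, b = pa[key], pb[key]
            if a >= thr and b >= thr:
                out["shared"].append(key)
            elif a >= thr:
                out["selective_a"].append(key)
            elif b >= thr:
                out["selective_b"].append(key)
            else:
                out["neither"].append(key)
        return out

    def to_json_dict(self) -> dict:
        def keyed(d: dict[ResidueKey, float]) -> dict[str, float]:
            return {f"{seq}:{name}": v for (seq, name), v in sorted(d.items())}

        return {
            "contact_probabilities": {
                label: keyed(d)
                for label, d in self.contact_probabilities.items()
            },
            "ligand_sigma": dict(self.ligand_sigma),
            "bridge_residue": (
                list(self.bridge_residue) if self.bridge_residue else None
            ),
            "bridge_occupancy": self.bridge_occupancy,
            "mean_separations": keyed(self.mean_separations),
            "selectivity_threshold": self.selectivity_threshold,
        }


# -- base geometry (local frame of subunit 0) --------------------------------


def _rotation_z(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


class _BaseGeometry:
    """Frame-independent scaffold of one subunit, in its local frame."""

    RADIUS = 14.0  # Å, ligand centre distance from the symmetry axis
    BACKBONE_RADIUS = 9.0  # Å, backbone anchors from the ligand centre

    def __init__(self, spec: SyntheticSpec):
        self.spec = spec
        self.centre = np.array([self.RADIUS, 0.0, 0.0])
        # headgroup triad (indices 0..2 of the ligand) + apolar tail
        head = np.array(
            [[0.0, 0.0, 0.9], [0.9, 0.5, -0.5], [-0.6, 0.9, -0.4]]
        )
        tail = np.array(
            [
                [-1.4 * (k + 1), 0.4 * (-1) ** k, -0.8 - 0.1 * k]
                for k in range(spec.ligand_tail_atoms)
            ]
        ).reshape(-1, 3)
        self.ligand_base = self.centre + np.vstack([head, tail])
        self.o1_index = 1  # ligand polar oxygen anchoring the water bridge
        n = spec.residues_per_subunit
        # residue directions fan outward from the ligand over a wide cone
        theta = np.linspace(-1.7, 1.7, n)
        phi = 0.6 * np.sin(np.linspace(0.0, 3.0 * np.pi, n))
        self.u = np.stack(
            [
                np.cos(phi) * np.cos(theta),
                np.cos(phi) * np.sin(theta),
                np.sin(phi),
            ],
            axis=1,
        )
        # orthonormal frames (u, p1, p2) per residue
        helper = np.where(
            np.abs(self.u[:, 2:3]) < 0.9,
            np.array([0.0, 0.0, 1.0]),
            np.array([1.0, 0.0, 0.0]),
        )
        p1 = np.cross(self.u, helper)
        p1 /= np.linalg.norm(p1, axis=1, keepdims=True)
        p2 = np.cross(self.u, p1)
        self.p1, self.p2 = p1, p2
        # fixed backbone proxies: N, CA, C, O around an anchor on the ray
        anchor = self.centre + self.BACKBONE_RADIUS * self.u
        self.backbone_base = np.stack(
            [
                anchor + 1.2 * p1,
                anchor,
                anchor + 1.2 * p2,
                anchor + 1.2 * p2 + 1.1 * p1,
            ],
            axis=1,
        )  # (n_res, 4, 3)
        self.water_rest = self.centre + np.array([0.0, 0.0, 25.0])


def _build_topology(spec: SyntheticSpec, label: str) -> Topology:
    resname_ligand = label[:3].upper()
    records: list[AtomRecord] = []
    atom_id = 1

    def add(name, element, seq, resname, chain, category):
        nonlocal atom_id
        records.append(
            AtomRecord(
                atom_id=atom_id,
                atom_name=name,
                element=element,
                mass=mass_for_element(element),
                residue_seq=seq,
                residue_name=resname,
                subunit_id=chain,
                category=category,
            )
        )
        atom_id += 1

    for s in range(spec.n_subunits):
        chain = _CHAINS[s]
        for seq in spec.residue_seqs():
            resname = spec.residue_name(seq)
            for bb in ("N", "CA", "C", "O"):
                add(bb, bb[0], seq, resname, chain, "protein_backbone")
            if seq == spec.bridge_residue_seq:
                side = [("OE1", "O"), ("CG", "C"), ("CB", "C")]
            else:
                side = [("CB", "C"), ("CG", "C"), ("CD", "C")]
            for name, elem in side:
                add(name, elem, seq, resname, chain, "protein_sidechain")
        lig_names = ["P1", "O1", "O2"] + [
            f"C{k + 1}" for k in range(spec.ligand_tail_atoms)
        ]
        lig_elements = ["P", "O", "O"] + ["C"] * spec.ligand_tail_atoms
        for name, elem in zip(lig_names, lig_elements):
            add(name, elem, LIGAND_RESIDUE_SEQ, resname_ligand, chain, "ligand")
        add("O", "O", WATER_RESIDUE_SEQ, "HOH", chain, "water")
    return Topology(records)


def _frame_coords(
    spec: SyntheticSpec,
    geometry: _BaseGeometry,
    label: str,
    species_idx: int,
    t: int,
    s: int,
) -> np.ndarray:
    """Coordinates of one subunit in one frame (local order, global frame)."""
    rng = np.random.default_rng(
        np.random.SeedSequence(spec.seed, spawn_key=(species_idx, t, s))
    )
    n_res = spec.residues_per_subunit
    n_lig = 3 + spec.ligand_tail_atoms
    sigma_lig = spec.ligand_sigma.get(label, 0.0)

    jitter = rng.normal(0.0, 1.0, (n_lig, 3))
    lig = geometry.ligand_base + (sigma_lig * jitter if t > 0 else 0.0)
    head = lig[:3]

    # nearest-in-direction headgroup atom per residue (projection argmax)
    proj = head @ geometry.u.T  # (3, n_res)
    hstar = head[np.argmax(proj, axis=0)]  # (n_res, 3)

    # designed minimum distance per residue
    d = np.empty(n_res)
    states = rng.random(n_res)
    d_in = rng.uniform(*spec.contact_d_in, n_res)
    d_out = rng.uniform(*spec.contact_d_out, n_res)
    sep_noise = rng.normal(0.0, 1.0, n_res)
    for i, seq in enumerate(spec.residue_seqs()):
        if seq == spec.bridge_residue_seq:
            d[i] = 3.2 + 1.2 * states[i]  # pinned inside the shell
            hstar[i] = lig[geometry.o1_index]
        elif seq in spec.separation_design:
            mean, sd = spec.separation_design[seq]
            d[i] = max(mean + sd * sep_noise[i], 1.5)
        else:
            p = spec.contact_design.get(seq, {}).get(
                label, spec.default_contact_p
            )
            d[i] = d_in[i] if states[i] < p else d_out[i]

    u, p1 = geometry.u, geometry.p1
    side = np.stack(
        [
            hstar + d[:, None] * u,
            hstar + (d + 1.5)[:, None] * u + 0.3 * p1,
            hstar + (d + 2.9)[:, None] * u - 0.3 * p1,
        ],
        axis=1,
    )  # (n_res, 3, 3); atom 0 realises the designed minimum distance

    backbone = geometry.backbone_base.copy()
    protein_noise = rng.normal(0.0, 1.0, (n_res, 7, 3))
    if t > 0 and spec.protein_sigma > 0:
        backbone = backbone + spec.protein_sigma * protein_noise[:, :4]
        side = side + spec.protein_sigma * protein_noise[:, 4:]

    bridge_on = rng.random() < spec.bridge_occupancy
    if spec.bridge_residue_seq is not None:
        rb = spec.residue_seqs().index(spec.bridge_residue_seq)
        oe1 = side[rb, 0]
        o_lig = lig[geometry.o1_index]
        if bridge_on:
            water = 0.5 * (oe1 + o_lig)
        else:
            water = o_lig + (d[rb] + 9.0) * u[rb]
    else:
        water = geometry.water_rest

    local = np.vstack(
        [
            np.concatenate([backbone, side], axis=1).reshape(-1, 3),
            lig,
            water[None, :],
        ]
    )
    rot = _rotation_z(s * 2.0 * np.pi / spec.n_subunits)
    return local @ rot.T


def generate_ensemble(
    spec: SyntheticSpec, ligand_label: str | None = None
) -> tuple[Ensemble, GroundTruth]:
    """Generate the ensemble for one ligand species, plus its ground truth.

    Deterministic given ``(spec, seed)``; the PRNG substream of each
    (species, frame, subunit) triple is derived from the seed, so the
    result does not depend on generation order.
    """
    label = ligand_label or spec.ligands[0]
    if label not in spec.ligands:
        raise ValueError(f"unknown ligand label {label!r}")
    species_idx = spec.ligands.index(label)
    geometry = _BaseGeometry(spec)
    topology = _build_topology(spec, label)
    per_subunit = topology.n_atoms // spec.n_subunits
    coords = np.empty((spec.n_frames, topology.n_atoms, 3))
    for t in range(spec.n_frames):
        for s in range(spec.n_subunits):
            coords[t, s * per_subunit : (s + 1) * per_subunit] = _frame_coords(
                spec, geometry, label, species_idx, t, s
            )
    return Ensemble(topology, coords), ground_truth_for(spec)


def ground_truth_for(spec: SyntheticSpec) -> GroundTruth:
    """Designed values implied by a spec (identical for every species)."""
    mean_in = 0.5 * sum(spec.contact_d_in)
    mean_out = 0.5 * sum(spec.contact_d_out)
    probabilities: dict[str, dict[ResidueKey, float]] = {}
    separations: dict[ResidueKey, float] = {}
    for label in spec.ligands:
        probabilities[label] = {
            spec.residue_key(seq): spec.contact_probability(seq, label)
            for seq in spec.residue_seqs()
        }
    first_label = spec.ligands[0]
    for seq in spec.residue_seqs():
        key = spec.residue_key(seq)
        if seq == spec.bridge_residue_seq:
            continue  # its anchor atom is not guaranteed to be the minimum
        if seq in spec.separation_design:
            separations[key] = spec.separation_design[seq][0]
        else:
            p = probabilities[first_label][key]
            separations[key] = p * mean_in + (1.0 - p) * mean_out
    bridge_key = (
        spec.residue_key(spec.bridge_residue_seq)
        if spec.bridge_residue_seq is not None
        else None
    )
    return GroundTruth(
        contact_probabilities=probabilities,
        ligand_sigma={l: spec.ligand_sigma.get(l, 0.0) for l in spec.ligands},
        bridge_residue=bridge_key,
        bridge_occupancy=spec.bridge_occupancy,
        mean_separations=separations,
    )


def generate_study(
    spec: SyntheticSpec,
) -> tuple[dict[str, Ensemble], GroundTruth]:
    """One ensemble per ligand species, sharing a single ground truth."""
    ensembles = {}
    truth = ground_truth_for(spec)
    for label in spec.ligands:
        ensembles[label], _ = generate_ensemble(spec, label)
    return ensembles, truth


def ligand_spec_for(spec: SyntheticSpec, label: str) -> LigandSpec:
    """The :class:`LigandSpec` matching a generated ensemble."""
    return LigandSpec(
        label=label,
        residues=frozenset(
            (_CHAINS[s], LIGAND_RESIDUE_SEQ) for s in range(spec.n_subunits)
        ),
        headgroup_atom_names=HEADGROUP_ATOM_NAMES,
    )


def fixture_classify_rules(labels: tuple[str, ...]) -> ClassifyRules:
    """Classification rules recognising the generated ligand residues."""
    return ClassifyRules(
        ligand_resnames=frozenset(l[:3].upper() for l in labels)
    )


def write_fixture(
    ensembles: dict[str, Ensemble] | Ensemble,
    ground_truth: GroundTruth,
    directory: str | Path,
    spec: SyntheticSpec | None = None,
    dialect: str = "pdb_multimodel",
) -> dict[str, Path]:
    """Write ensembles, ligand specs and the ground-truth sidecar.

    Returns a map of logical names to written paths.  Fixtures are
    re-readable with :func:`ligprof.io.read_structure_ensemble` using
    :func:`fixture_classify_rules`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if isinstance(ensembles, Ensemble):
        ensembles = {"ensemble": ensembles}
    written: dict[str, Path] = {}
    suffix = ".pdb" if dialect == "pdb_multimodel" else ".tsv"
    for label, ensemble in ensembles.items():
        path = directory / f"{label}{suffix}"
        write_structure_ensemble(ensemble, path, dialect=dialect)
        written[f"{label}_ensemble"] = path
        if spec is not None and label in spec.ligands:
            lig_path = directory / f"{label}.ligand.yaml"
            write_ligand_spec(ligand_spec_for(spec, label), lig_path)
            written[f"{label}_ligand"] = lig_path
    gt_path = directory / "ground_truth.json"
    with open(gt_path, "w") as fh:
        json.dump(ground_truth.to_json_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    written["ground_truth"] = gt_path
    return written


def fixture_checksum(directory: str | Path) -> str:
    """SHA-256 over all fixture files (sorted); a determinism probe."""
    directory = Path(directory)
    digest = hashlib.sha256()
    for path in sorted(p for p in directory.iterdir() if p.is_file()):
        digest.update(path.name.encode())
        digest.update(path.read_bytes())
    return digest.hexdigest()
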