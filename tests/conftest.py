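"""Shared fixtures: hand-built toy ensembles and brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from ligprof.core import AtomRecord, Ensemble, LigandSpec, Topology
from ligprof.synthetic import SyntheticSpec, generate_ensemble, ligand_spec_for


def make_ensemble(atoms: list[dict], frames: np.ndarray) -> Ensemble:
    """Build an ensemble from compact atom dicts and (T, N, 3) coords.

    Each atom dict needs: name, element, seq, resname, chain, category;
    mass defaults from the element table.
    """
    from ligprof.core import mass_for_element

    records = [
        AtomRecord(
            atom_id=i + 1,
            atom_name=a["name"],
            element=a["element"],
            mass=a.get("mass", mass_for_element(a["element"])),
            residue_seq=a["seq"],
            residue_name=a["resname"],
            subunit_id=a["chain"],
            category=a["category"],
        )
        for i, a in enumerate(atoms)
    ]
    return Ensemble(Topology(records), np.asarray(frames, dtype=float))


def toy_contact_system(side_positions: np.ndarray, head_positions: np.ndarray):
    """One sidechain residue + one single-headgroup ligand on chain A.

    ``side_positions`` and ``head_positions`` are (T, 3) per-frame
    positions of the lone sidechain atom and the lone headgroup atom.
    """
    atoms = [
        dict(name="CA", element="C", seq=10, resname="LEU", chain="A",
             category="protein_backbone"),
        dict(name="CB", element="C", seq=10, resname="LEU", chain="A",
             category="protein_sidechain"),
        dict(name="P1", element="P", seq=900, resname="LIG", chain="A",
             category="ligand"),
    ]
    side = np.asarray(side_positions, dtype=float)
    head = np.asarray(head_positions, dtype=float)
    T = side.shape[0]
    frames = np.zeros((T, 3, 3))
    frames[:, 0] = side + np.array([0.0, 0.0, 20.0])  # backbone far away
    frames[:, 1] = side
    frames[:, 2] = head
    ensemble = make_ensemble(atoms, frames)
    ligand = LigandSpec(
        label="LIG",
        residues=frozenset({("A", 900)}),
        headgroup_atom_names=frozenset({"P1"}),
    )
    return ensemble, ligand


def random_contact_ensemble(rng: np.random.Generator, n_frames: int = 1):
    """Random <=200-atom single-subunit system for oracle comparisons."""
    n_residues = int(rng.integers(10, 31))
    n_head = int(rng.integers(2, 6))
    atoms = []
    for r in range(n_residues):
        seq = 100 + r
        for name in ("N", "CA", "C", "O"):
            atoms.append(dict(name=name, element=name[0], seq=seq,
                              resname="LEU", chain="A",
                              category="protein_backbone"))
        for name in ("CB", "CG"):
            atoms.append(dict(name=name, element="C", seq=seq,
                              resname="LEU", chain="A",
                              category="protein_sidechain"))
    for k in range(n_head):
        atoms.append(dict(name=f"O{k + 1}", element="O", seq=900,
                          resname="LIG", chain="A", category="ligand"))
    coords = rng.uniform(0.0, 20.0, (n_frames, len(atoms), 3))
    ensemble = make_ensemble(atoms, coords)
    ligand = LigandSpec(
        label="LIG",
        residues=frozenset({("A", 900)}),
        headgroup_atom_names=frozenset(f"O{k + 1}" for k in range(n_head)),
    )
    return ensemble, ligand


def brute_force_contact_set(
    ensemble: Ensemble, ligand: LigandSpec, cutoff: float, frame: int
) -> set:
    """O(N^2) reference: {(residue_key, subunit)} in contact in a frame."""
    topo = ensemble.topology
    out = set()
    for su in ligand.subunits:
        hg = ligand.headgroup_indices(topo, su)
        sc = topo.select(subunit=su, category="protein_sidechain",
                         heavy_only=True)
        if hg.size == 0 or sc.size == 0:
            continue
        d = cdist(ensemble.coords[frame, sc], ensemble.coords[frame, hg])
        hit = d.min(axis=1) <= cutoff
        for i in np.flatnonzero(hit):
            key = (int(topo.residue_seq[sc[i]]),
                   str(topo.residue_name[sc[i]]))
            out.add((key, su))
    return out


def contact_set_from_profile(ensemble, ligand, cutoff, frame) -> set:
    """Contact set of one frame via the package's accelerated path."""
    from ligprof.contacts import contact_frequencies

    one = Ensemble(ensemble.topology, ensemble.coords[frame : frame + 1])
    profile = contact_frequencies(one, ligand, cutoff=cutoff)
    return {
        (key, su)
        for (key, su), f in profile.per_subunit.items()
        if f > 0.5
    }


def random_rigid_motion(rng: np.random.Generator):
    """A uniformly random proper rotation and a random translation."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(random_state=np.random.RandomState(
        int(rng.integers(0, 2**31 - 1))
    )).as_matrix()
    trans = rng.uniform(-20.0, 20.0, 3)
    return rot, trans


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    """Reduced-size study spec for fast unit tests."""
    return SyntheticSpec(
        n_frames=60, seed=7, residues_per_subunit=12, bridge_residue_seq=512
    )


@pytest.fixture(scope="session")
def small_study(small_spec):
    """(ensembles per species, ground truth, ligand specs) at small T."""
    ens_pi, truth = generate_ensemble(small_spec, "PI")
    ens_pip2, _ = generate_ensemble(small_spec, "PIP2")
    ligands = {
        "PI": ligand_spec_for(small_spec, "PI"),
        "PIP2": ligand_spec_for(small_spec, "PIP2"),
    }
    return {"PI": ens_pi, "PIP2": ens_pip2}, truth, ligands
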