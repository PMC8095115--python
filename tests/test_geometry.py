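"""Minimum distances, Kabsch superposition and ligand RMSD."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import cdist

from ligprof.core import DegenerateGeometryError, Ensemble
from ligprof.geometry import (
    mean_separation_report,
    min_distance_series,
    rmsd_series,
    superpose,
)
from ligprof.synthetic import SyntheticSpec, generate_ensemble, ligand_spec_for

from conftest import random_contact_ensemble, random_rigid_motion, toy_contact_system


class TestMinDistance:
    def test_3_4_5_triangle(self):
        ensemble, ligand = toy_contact_system(
            np.array([[0.0, 0.0, 0.0]]), np.array([[3.0, 4.0, 0.0]])
        )
        series = min_distance_series(ensemble, [(10, "LEU")], ligand)
        assert series[(10, "LEU")].values[0, 0] == pytest.approx(5.0)

    def test_coincident_atoms_zero(self):
        ensemble, ligand = toy_contact_system(
            np.zeros((1, 3)), np.zeros((1, 3))
        )
        series = min_distance_series(ensemble, [(10, "LEU")], ligand)
        assert series[(10, "LEU")].values[0, 0] == 0.0

    def test_matches_brute_force_over_random_frames(self):
        """50 seeded frames: equals the O(N^2) pairwise minimum."""
        rng = np.random.default_rng(77)
        ensemble, ligand = random_contact_ensemble(rng, n_frames=50)
        topo = ensemble.topology
        key = (100, "LEU")
        series = min_distance_series(ensemble, [key], ligand)[key]
        sc = topo.select(subunit="A", residue_seq=100,
                         category="protein_sidechain", heavy_only=True)
        hg = ligand.headgroup_indices(topo, "A")
        for t in range(50):
            expected = cdist(
                ensemble.coords[t, sc], ensemble.coords[t, hg]
            ).min()
            assert series.values[t, 0] == pytest.approx(expected, abs=1e-12)

    def test_glycine_like_residue_reports_error_entry(self):
        ensemble, ligand = toy_contact_system(np.zeros((1, 3)), np.zeros((1, 3)))
        series = min_distance_series(
            ensemble, [(10, "LEU"), (99, "GLY")], ligand
        )
        assert isinstance(series[(99, "GLY")], str)  # per-residue error
        assert not isinstance(series[(10, "LEU")], str)

    def test_designed_separations_recovered(self):
        """Designed 3 Å vs 8 Å mean separations recovered within 0.1 Å."""
        spec = SyntheticSpec(
            n_frames=500, seed=21, residues_per_subunit=12,
            bridge_residue_seq=None,
            separation_design={503: (3.0, 0.3), 507: (8.0, 0.3)},
        )
        ensemble, truth = generate_ensemble(spec, "PI")
        ligand = ligand_spec_for(spec, "PI")
        near, far = spec.residue_key(503), spec.residue_key(507)
        series = min_distance_series(ensemble, [near, far], ligand)
        assert series[near].overall_mean == pytest.approx(3.0, abs=0.1)
        assert series[far].overall_mean == pytest.approx(8.0, abs=0.1)
        report = mean_separation_report(series, reference=near, margin=4.0)
        flagged = report[report["far"]]
        assert list(flagged["residue_seq"]) == [507]

    def test_mean_report_constant_and_threshold(self):
        ensemble, ligand = toy_contact_system(
            np.zeros((6, 3)), np.tile([2.0, 0, 0], (6, 1))
        )
        series = min_distance_series(ensemble, [(10, "LEU")], ligand)
        report = mean_separation_report(series)
        assert report["mean_distance"].iloc[0] == pytest.approx(2.0)


class TestSuperpose:
    def test_identity(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(10, 3))
        rot, trans, rmsd = superpose(pts, pts)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(trans, 0.0, atol=1e-12)
        assert rmsd < 1e-12

    def test_exact_rigid_motion_recovered(self):
        rng = np.random.default_rng(2)
        ref = rng.normal(size=(25, 3))
        angle = np.pi / 2
        rot_true = np.array(
            [[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]]
        )
        trans_true = np.array([1.0, 2.0, 3.0])
        mobile = ref @ rot_true.T + trans_true
        rot, trans, rmsd = superpose(mobile, ref)
        assert rmsd < 1e-10
        np.testing.assert_allclose(rot @ rot_true, np.eye(3), atol=1e-9)

    def test_no_reflection_for_chiral_cloud(self):
        rng = np.random.default_rng(3)
        ref = rng.normal(size=(12, 3))
        mirrored = ref * np.array([-1.0, 1.0, 1.0])
        rot, _, _ = superpose(mirrored, ref)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_gaussian_noise_fit_rmsd(self):
        """Fit RMSD of noisy clouds matches sigma*sqrt(3) within 10%."""
        rng = np.random.default_rng(4)
        sigma = 0.1
        rmsds = []
        for _ in range(50):
            ref = rng.uniform(-5, 5, (50, 3))
            rot_true, trans_true = random_rigid_motion(rng)
            mobile = (ref + rng.normal(0, sigma, ref.shape)) @ rot_true.T
            mobile = mobile + trans_true
            _, _, rmsd = superpose(mobile, ref)
            rmsds.append(rmsd)
        assert np.mean(rmsds) == pytest.approx(sigma * np.sqrt(3), rel=0.10)

    def test_transform_attains_reported_rmsd(self):
        rng = np.random.default_rng(5)
        ref = rng.normal(size=(30, 3))
        mobile = ref + rng.normal(0, 0.5, ref.shape)
        rot, trans, rmsd = superpose(mobile, ref)
        applied = mobile @ rot.T + trans
        direct = np.sqrt(((applied - ref) ** 2).sum(axis=1).mean())
        assert direct == pytest.approx(rmsd, abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        line = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0]])
        with pytest.raises(DegenerateGeometryError):
            superpose(line + 0.0, line)
        with pytest.raises(DegenerateGeometryError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_matches_mdanalysis_rotation(self):
        """Independent oracle: MDAnalysis alignment gives the same fit."""
        from MDAnalysis.analysis.align import rotation_matrix

        rng = np.random.default_rng(6)
        ref = rng.normal(size=(40, 3))
        mobile = ref + rng.normal(0, 0.3, ref.shape)
        rot, _, rmsd = superpose(mobile, ref)
        mda_rot, mda_rmsd = rotation_matrix(
            mobile - mobile.mean(axis=0), ref - ref.mean(axis=0)
        )
        assert rmsd == pytest.approx(mda_rmsd, abs=1e-9)
        np.testing.assert_allclose(rot, mda_rot, atol=1e-6)


class TestRMSDSeries:
    def test_reference_frame_is_zero(self, small_study):
        ensembles, _, ligands = small_study
        series = rmsd_series(ensembles["PI"], ligands["PI"])
        np.testing.assert_allclose(series.values[0], 0.0, atol=1e-9)
        assert (series.values >= 0).all()

    def test_frozen_ensemble_rmsd_zero(self):
        spec = SyntheticSpec(
            n_frames=5, seed=13, residues_per_subunit=6,
            bridge_residue_seq=None, protein_sigma=0.0,
            ligand_sigma={"PI": 0.0, "PIP2": 0.0},
        )
        ensemble, _ = generate_ensemble(spec, "PI")
        series = rmsd_series(ensemble, ligand_spec_for(spec, "PI"))
        np.testing.assert_allclose(series.values, 0.0, atol=1e-9)

    def test_rigid_comotion_scores_zero(self):
        """A ligand translated with its whole subunit has zero RMSD."""
        spec = SyntheticSpec(
            n_frames=2, seed=17, residues_per_subunit=6,
            bridge_residue_seq=None, protein_sigma=0.0,
            ligand_sigma={"PI": 0.0, "PIP2": 0.0},
        )
        ensemble, _ = generate_ensemble(spec, "PI")
        coords = ensemble.coords.copy()
        coords[1] = coords[1] + np.array([3.0, -2.0, 1.0])
        moved = Ensemble(ensemble.topology, coords)
        series = rmsd_series(moved, ligand_spec_for(spec, "PI"))
        np.testing.assert_allclose(series.values[1], 0.0, atol=1e-9)

    def test_global_rigid_motion_invariance(self, small_study):
        ensembles, _, ligands = small_study
        rng = np.random.default_rng(19)
        rot, trans = random_rigid_motion(rng)
        moved = Ensemble(
            ensembles["PI"].topology, ensembles["PI"].coords @ rot.T + trans
        )
        a = rmsd_series(ensembles["PI"], ligands["PI"])
        b = rmsd_series(moved, ligands["PI"])
        np.testing.assert_allclose(a.values, b.values, atol=1e-8)

    def test_noise_sigma_closed_form(self):
        """Ligand jitter sigma=1.0 gives mean RMSD near sqrt(3)."""
        spec = SyntheticSpec(
            n_frames=100, seed=23, residues_per_subunit=6,
            bridge_residue_seq=None, protein_sigma=0.0,
            ligand_sigma={"PI": 1.0, "PIP2": 1.0}, ligand_tail_atoms=47,
        )
        ensemble, _ = generate_ensemble(spec, "PI")
        series = rmsd_series(ensemble, ligand_spec_for(spec, "PI"))
        assert series.time_average == pytest.approx(np.sqrt(3.0), rel=0.10)

    def test_stability_ordering_small(self):
        """sigma 0.5 vs 2.0 pose noise orders the time-averaged RMSD."""
        wins = 0
        for seed in range(10):
            spec = SyntheticSpec(
                n_frames=30, seed=seed, residues_per_subunit=6,
                bridge_residue_seq=None,
            )
            ens_a, _ = generate_ensemble(spec, "PI")
            ens_b, _ = generate_ensemble(spec, "PIP2")
            ra = rmsd_series(ens_a, ligand_spec_for(spec, "PI"))
            rb = rmsd_series(ens_b, ligand_spec_for(spec, "PIP2"))
            wins += ra.time_average < rb.time_average
        assert wins == 10

    def test_bad_reference_frame_rejected(self, small_study):
        ensembles, _, ligands = small_study
        with pytest.raises(IndexError):
            rmsd_series(ensembles["PI"], ligands["PI"], reference_frame=10**6)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 1_000))
    def test_global_mode_agrees_for_symmetric_noise_free_protein(self, seed):
        """Per-subunit and global alignment coincide when the protein
        scaffold is identical in every frame."""
        spec = SyntheticSpec(
            n_frames=4, seed=seed, residues_per_subunit=5,
            bridge_residue_seq=None, protein_sigma=0.0,
        )
        ensemble, _ = generate_ensemble(spec, "PI")
        lig = ligand_spec_for(spec, "PI")
        a = rmsd_series(ensemble, lig, mode="per_subunit")
        b = rmsd_series(ensemble, lig, mode="global")
        np.testing.assert_allclose(a.values, b.values, atol=1e-8)
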