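"""Density maps: mass conservation, averaging linearity, correlation
closed forms, water occupancy and bridge statistics."""

import numpy as np
import pytest

from ligprof.core import ConfigurationError, DensityMap, SelectionError
from ligprof.density import (
    atomic_density_map,
    map_correlation,
    water_bridge_frequency,
    water_occupancy_map,
)
from ligprof.synthetic import SyntheticSpec, generate_ensemble, ligand_spec_for

from conftest import make_ensemble


def _single_atom(positions, element="C", mass=None):
    atom = dict(name="X1", element=element, seq=1, resname="LIG",
                chain="A", category="ligand")
    if mass is not None:
        atom["mass"] = mass
    return make_ensemble([atom], np.asarray(positions, float).reshape(-1, 1, 3))


class TestAtomicDensityMap:
    def test_single_atom_mass_conservation(self):
        ensemble = _single_atom([[0.0, 0.0, 0.0]], mass=12.0)
        dmap = atomic_density_map(ensemble, np.array([0]))
        assert dmap.integral() == pytest.approx(12.0, rel=0.01)
        assert dmap.spacing == 0.5

    def test_two_identical_frames_average_to_one_frame_map(self):
        one = _single_atom([[1.0, 2.0, 3.0]])
        two = _single_atom([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        m1 = atomic_density_map(one, np.array([0]))
        m2 = atomic_density_map(two, np.array([0]))
        np.testing.assert_allclose(m2.values, m1.values)
        assert m2.n_frames_averaged == 2

    def test_two_atom_integral_and_peaks(self):
        atoms = [
            dict(name="C1", element="C", seq=1, resname="LIG", chain="A",
                 category="ligand", mass=12.0),
            dict(name="O1", element="O", seq=1, resname="LIG", chain="A",
                 category="ligand", mass=16.0),
        ]
        pos = np.array([[[0.0, 0, 0], [6.0, 0, 0]]])
        ensemble = make_ensemble(atoms, pos)
        dmap = atomic_density_map(ensemble, np.array([0, 1]))
        assert dmap.integral() == pytest.approx(28.0, rel=0.01)
        # the global maximum sits within one voxel of the heavier atom
        idx = np.unravel_index(np.argmax(dmap.values), dmap.dims)
        peak = dmap.origin + dmap.spacing * np.array(idx)
        np.testing.assert_allclose(peak, [6.0, 0.0, 0.0], atol=dmap.spacing)
        # and the lighter atom's centre is a local peak of comparable mass
        centre_idx = np.rint((np.zeros(3) - dmap.origin) / dmap.spacing)
        i, j, k = centre_idx.astype(int)
        neighbourhood = dmap.values[i - 3 : i + 4, j - 3 : j + 4, k - 3 : k + 4]
        assert dmap.values[i, j, k] == neighbourhood.max()

    def test_frame_averaging_linearity(self):
        """Map over T frames equals the mean of per-frame maps exactly."""
        rng = np.random.default_rng(31)
        pos = rng.uniform(0, 4, (3, 1, 3))
        ensemble = _single_atom(pos)
        full = atomic_density_map(ensemble, np.array([0]))
        partial = [
            atomic_density_map(ensemble, np.array([0]), frames=np.array([t]))
            for t in range(3)
        ]
        # per-frame maps share the ensemble-wide grid, so the average is exact
        mean = np.mean([p.values for p in partial], axis=0)
        np.testing.assert_allclose(full.values, mean, atol=1e-12)

    def test_hydrogens_and_empty_selection_rejected(self):
        ensemble = _single_atom([[0.0, 0, 0]], element="H", mass=1.008)
        with pytest.raises(SelectionError):
            atomic_density_map(ensemble, np.array([0]))


class TestMapCorrelation:
    def test_self_correlation_is_one(self):
        ensemble = _single_atom([[0.0, 0, 0]])
        dmap = atomic_density_map(ensemble, np.array([0]))
        comparison = map_correlation(dmap, dmap)
        assert comparison.correlation == pytest.approx(1.0, abs=1e-9)
        assert comparison.correlation_about_mean == pytest.approx(1.0, abs=1e-9)

    def test_negation_about_mean_gives_minus_one(self):
        rng = np.random.default_rng(37)
        values = rng.uniform(0.2, 0.8, (6, 6, 6))
        a = DensityMap(origin=np.zeros(3), spacing=1.0, values=values)
        b = DensityMap(
            origin=np.zeros(3), spacing=1.0,
            values=2 * values.mean() - values,
        )
        comparison = map_correlation(a, b)
        assert comparison.correlation_about_mean == pytest.approx(-1.0, abs=1e-9)

    @pytest.mark.parametrize("delta", [1.0, 2.0, 4.0])
    def test_gaussian_offset_closed_form(self, delta):
        """Correlation of unit Gaussians matches exp(-d^2/(4 sigma^2))."""
        a = atomic_density_map(
            _single_atom([[0.0, 0, 0]]), np.array([0]), weight_mode="occupancy"
        )
        b = atomic_density_map(
            _single_atom([[delta, 0, 0]]), np.array([0]),
            weight_mode="occupancy",
        )
        expected = np.exp(-(delta**2) / 4.0)
        measured = map_correlation(a, b).correlation
        assert measured == pytest.approx(expected, rel=0.02)

    def test_correlation_decreases_with_offset(self):
        values = []
        for delta in (0.0, 1.0, 2.0, 4.0):
            a = atomic_density_map(
                _single_atom([[0.0, 0, 0]]), np.array([0]),
                weight_mode="occupancy",
            )
            b = atomic_density_map(
                _single_atom([[delta, 0, 0]]), np.array([0]),
                weight_mode="occupancy",
            )
            values.append(map_correlation(a, b).correlation)
        assert values == sorted(values, reverse=True)
        assert values[0] == pytest.approx(1.0, abs=1e-9)

    def test_disjoint_maps_error(self):
        a = DensityMap(origin=np.zeros(3), spacing=1.0, values=np.ones((4, 4, 4)))
        b = DensityMap(origin=np.full(3, 100.0), spacing=1.0,
                       values=np.ones((4, 4, 4)))
        with pytest.raises(ConfigurationError, match="overlap"):
            map_correlation(a, b)

    def test_symmetry_after_bidirectional_resampling(self):
        a = atomic_density_map(
            _single_atom([[0.0, 0, 0]]), np.array([0]), weight_mode="occupancy"
        )
        b = atomic_density_map(
            _single_atom([[1.5, 0.3, -0.2]]), np.array([0]),
            weight_mode="occupancy",
        )
        ab = map_correlation(a, b).correlation
        ba = map_correlation(b, a).correlation
        assert abs(ab - ba) < 0.02


def _bridge_fixture(d_res, d_lig):
    """Polar residue atom at origin-side, ligand polar atom, one water."""
    atoms = [
        dict(name="CA", element="C", seq=50, resname="GLN", chain="A",
             category="protein_backbone"),
        dict(name="OE1", element="O", seq=50, resname="GLN", chain="A",
             category="protein_sidechain"),
        dict(name="O1", element="O", seq=900, resname="LIG", chain="A",
             category="ligand"),
        dict(name="O", element="O", seq=1000, resname="HOH", chain="A",
             category="water"),
    ]
    frames = np.zeros((1, 4, 3))
    frames[0, 0] = [0.0, 0.0, 15.0]
    frames[0, 1] = [0.0, 0.0, 0.0]          # residue polar atom
    frames[0, 2] = [10.0, 0.0, 0.0]         # ligand polar atom
    frames[0, 3] = [d_res, 0.0, 0.0]
    # place water so distances to the anchors are d_res and d_lig
    frames[0, 2] = [d_res + d_lig, 0.0, 0.0]
    ensemble = make_ensemble(atoms, frames)
    from ligprof.core import LigandSpec

    ligand = LigandSpec(
        label="LIG", residues=frozenset({("A", 900)}),
        headgroup_atom_names=frozenset({"O1"}),
    )
    return ensemble, ligand


class TestWaterBridge:
    def test_bridge_detected_at_hbond_distances(self):
        ensemble, ligand = _bridge_fixture(2.8, 2.8)
        report = water_bridge_frequency(ensemble, (50, "GLN"), ligand)
        assert report.bridge_frequency == 1.0

    def test_and_condition_fails_on_one_side(self):
        ensemble, ligand = _bridge_fixture(2.8, 5.0)
        report = water_bridge_frequency(ensemble, (50, "GLN"), ligand)
        assert report.bridge_frequency == 0.0

    def test_apolar_residue_rejected_by_name(self):
        ensemble, ligand = _bridge_fixture(2.8, 2.8)
        with pytest.raises(SelectionError, match="LEU999"):
            water_bridge_frequency(ensemble, (999, "LEU"), ligand)

    def test_designed_occupancy_recovered(self, small_study):
        ensembles, truth, ligands = small_study
        report = water_bridge_frequency(
            ensembles["PI"], truth.bridge_residue, ligands["PI"]
        )
        T = ensembles["PI"].n_frames
        n = T * len(report.subunit_ids)
        p = truth.bridge_occupancy
        se = np.sqrt(p * (1 - p) / n)
        assert abs(report.bridge_frequency - p) <= 4 * se


class TestWaterOccupancyMap:
    def test_constant_occupancy_independent_of_frame_count(self):
        maps = []
        for T in (1, 4):
            ensemble, ligand = _bridge_fixture(2.8, 2.8)
            frames = np.repeat(ensemble.coords, T, axis=0)
            from ligprof.core import Ensemble

            rep = Ensemble(ensemble.topology, frames)
            maps.append(
                water_occupancy_map(rep, (50, "GLN"), ligand, cutoff=6.0)
            )
        np.testing.assert_allclose(maps[0].values, maps[1].values, atol=1e-12)
        assert maps[0].integral() == pytest.approx(1.0, rel=0.01)

    def test_water_outside_one_shell_excluded(self):
        ensemble, ligand = _bridge_fixture(2.8, 10.0)
        dmap = water_occupancy_map(ensemble, (50, "GLN"), ligand, cutoff=6.0)
        assert dmap.integral() == pytest.approx(0.0, abs=1e-12)

    def test_designed_bridge_occupancy_in_map_integral(self, small_study):
        ensembles, truth, ligands = small_study
        dmap = water_occupancy_map(
            ensembles["PI"], truth.bridge_residue, ligands["PI"]
        )
        # integral ~ (bridged waters per frame) summed over 4 subunits
        n_sub = len(ensembles["PI"].topology.subunit_ids)
        T = ensembles["PI"].n_frames
        p = truth.bridge_occupancy
        se = np.sqrt(p * (1 - p) / T)  # per subunit
        expected = n_sub * p
        assert abs(dmap.integral() - expected) <= n_sub * 4 * se + 0.05
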