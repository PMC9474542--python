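"""Axis construction, insertion depth, trimming and RMSF."""

import numpy as np
import pytest

from fibrilsite import (AxisDefinition, anle138b_topology, build_toy_fibril,
                        depth_series, discard_equilibration, insertion_depth,
                        per_atom_rmsf, protofilament_axis, rmsf)
from fibrilsite.model_io import (FibrilModel, Trajectory, TrajectoryEnsemble,
                                 mass_of)
from tests.conftest import place_ligand_in_cavity


def _two_residue_model(nh_vectors):
    """Minimal model: one residue per layer, NH vectors as given."""
    names, elements, resids, chains, layers, coords = [], [], [], [], [], []
    for k, nh in enumerate(nh_vectors):
        n = np.array([0.0, 0.0, k * 0.48])
        for nm, xyz in (("N", n), ("H", n + 0.101 * np.asarray(nh))):
            names.append(nm)
            elements.append(nm[0])
            resids.append(k + 1)
            chains.append("A")
            layers.append(k)
            coords.append(xyz)
    return FibrilModel(np.array(names, dtype=object),
                       np.array(elements, dtype=object),
                       np.array(resids), np.array(chains, dtype=object),
                       np.array(coords), np.array(layers))


class TestProtofilamentAxis:
    def test_all_nh_along_z(self, fibril):
        axis = protofilament_axis(
            fibril, AxisDefinition(start_residue=1, stride=2,
                                   residue_span=(1, 8)))
        np.testing.assert_allclose(axis, [0, 0, 1], atol=1e-12)

    def test_stride_two_skips_antiparallel_set(self):
        # residues alternate NH = +z, -z; stride 2 from residue 1 keeps +z
        nh = [(0, 0, 1), (0, 0, -1), (0, 0, 1), (0, 0, -1)]
        model = _two_residue_model(nh)
        axis = protofilament_axis(
            model, AxisDefinition(start_residue=1, stride=2,
                                  residue_span=(1, 4)))
        np.testing.assert_allclose(axis, [0, 0, 1], atol=1e-12)

    def test_mean_of_tilted_vectors_normalised(self):
        s = 1 / np.sqrt(2)
        model = _two_residue_model([(s, 0, s), (-s, 0, s)])
        axis = protofilament_axis(
            model, AxisDefinition(start_residue=1, stride=1,
                                  residue_span=(1, 2)))
        # mean of the two unit vectors is (0, 0, s); normalised -> +z
        np.testing.assert_allclose(axis, [0, 0, 1], atol=1e-12)

    def test_unit_norm_always(self, fibril):
        axis = protofilament_axis(
            fibril, AxisDefinition(start_residue=1, stride=3,
                                   residue_span=(1, 8)))
        assert np.linalg.norm(axis) == pytest.approx(1.0, abs=1e-9)

    def test_sign_flips_with_layer_order(self):
        model = _two_residue_model([(0, 0, 1), (0, 0, 1)])
        flipped = FibrilModel(model.atom_names, model.elements, model.resids,
                              model.chain_ids, model.coords,
                              model.layer_index[::-1].copy())
        a = protofilament_axis(model, AxisDefinition(1, 1, (1, 2)))
        b = protofilament_axis(flipped, AxisDefinition(1, 1, (1, 2)))
        np.testing.assert_allclose(a, -b, atol=1e-12)

    def test_missing_amide_hydrogen_is_error(self, fibril):
        no_h = fibril.atom_names != "H"
        stripped = FibrilModel(fibril.atom_names[no_h],
                               fibril.elements[no_h], fibril.resids[no_h],
                               fibril.chain_ids[no_h], fibril.coords[no_h],
                               fibril.layer_index[no_h])
        with pytest.raises(ValueError, match="no amide hydrogen"):
            protofilament_axis(stripped, AxisDefinition(1, 2, (1, 8)))


class TestInsertionDepth:
    def test_coincident_coms_give_zero(self, ligand, fibril):
        tip_idx = fibril.layer_atom_indices(0)
        tip_com = np.average(fibril.coords[tip_idx], axis=0,
                             weights=fibril.masses[tip_idx])
        ring = ligand.group_indices("pyrazole_ring")
        w = ligand.masses[ring]
        frame = ligand.reference_coords - np.average(
            ligand.reference_coords[ring], axis=0, weights=w) + tip_com
        assert insertion_depth(frame, ligand, fibril, 0) \
            == pytest.approx(0.0, abs=1e-12)

    def test_three_four_five_triangle(self, ligand, fibril):
        tip_idx = fibril.layer_atom_indices(0)
        tip_com = np.average(fibril.coords[tip_idx], axis=0,
                             weights=fibril.masses[tip_idx])
        ring = ligand.group_indices("pyrazole_ring")
        w = ligand.masses[ring]
        frame = ligand.reference_coords - np.average(
            ligand.reference_coords[ring], axis=0, weights=w) \
            + tip_com + np.array([0.3, 0.4, 0.0])
        assert insertion_depth(frame, ligand, fibril, 0) \
            == pytest.approx(0.5, abs=1e-9)

    def test_matches_hand_computed_mass_weighted_centroid(self, fibril):
        # 5-atom pyrazole ring with unequal masses at chosen coordinates
        from fibrilsite.model_io import LigandTopology
        names = ("N1", "N2", "C3", "C4", "C5", "C1B", "C2B", "C3B", "C4B",
                 "C5B", "C6B", "O1", "O2", "C7B", "C1P", "C2P", "C3P",
                 "C4P", "C5P", "C6P", "BR")
        elements = tuple("N N C C C C C C C C C O O C C C C C C C BR".split())
        coords = np.zeros((21, 3))
        ring_xyz = np.array([[0, 0, 0], [0.1, 0, 0], [0.1, 0.1, 0],
                             [0, 0.1, 0], [0.05, 0.05, 0.1]])
        coords[:5] = ring_xyz
        top = LigandTopology(names, elements, {
            "pyrazole_ring": names[:5], "pyrazole_N": ("N1", "N2"),
            "benzodioxole_ring": names[5:14], "benzodioxole_O": ("O1", "O2"),
            "bromophenyl_ring": names[14:20], "halogen": ("BR",),
            "halogen_bonded_carbon": ("C3P",)})
        masses = np.array([mass_of(e) for e in elements[:5]])
        com = (ring_xyz * masses[:, None]).sum(axis=0) / masses.sum()
        tip_idx = fibril.layer_atom_indices(0)
        tip_com = np.average(fibril.coords[tip_idx], axis=0,
                             weights=fibril.masses[tip_idx])
        expected = np.linalg.norm(com - tip_com)
        assert insertion_depth(coords, top, fibril, 0) \
            == pytest.approx(expected, abs=1e-12)

    def test_invariant_under_rigid_motion(self, ligand, fibril):
        from scipy.spatial.transform import Rotation
        frame = place_ligand_in_cavity(ligand, fibril, z=2.0)
        d0 = insertion_depth(frame, ligand, fibril, 0)
        R = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        shift = np.array([1.0, -2.0, 0.5])
        moved = FibrilModel(fibril.atom_names, fibril.elements, fibril.resids,
                            fibril.chain_ids, fibril.coords @ R.T + shift,
                            fibril.layer_index)
        d1 = insertion_depth(frame @ R.T + shift, ligand, moved, 0)
        assert d1 == pytest.approx(d0, abs=1e-9)

    def test_depth_series_matches_per_frame_function(self, ligand, fibril,
                                                     hopping_run):
        _, ens, _ = hopping_run
        d = depth_series(ens, ligand, fibril)[0]
        for f in (0, 100, 2999):
            assert d[f] == pytest.approx(
                insertion_depth(ens.trajectories[0].coords[f], ligand,
                                fibril, 0), abs=1e-9)


class TestDiscardEquilibration:
    @pytest.mark.parametrize("n, fraction, kept", [
        (100, 0.25, 75),   # keep the last 75%
        (100, 0.0, 100),   # identity
        (3, 0.25, 3),      # floor(0.75) = 0 frames removed
    ])
    def test_frame_counts(self, ligand, n, fraction, kept):
        ens = TrajectoryEnsemble(
            tuple(ligand.atom_names), tuple(ligand.elements),
            [Trajectory(np.arange(n) * 0.1, np.zeros((n, 22, 3)))])
        out = discard_equilibration(ens, fraction)
        assert out.trajectories[0].n_frames == kept

    def test_bad_fraction_rejected(self, ligand):
        ens = TrajectoryEnsemble(
            tuple(ligand.atom_names), tuple(ligand.elements),
            [Trajectory(np.arange(4) * 0.1, np.zeros((4, 22, 3)))])
        with pytest.raises(ValueError):
            discard_equilibration(ens, 1.0)


def _fibril_ensemble(fibril, coords_list, dt=0.1):
    trajs = [Trajectory(np.arange(c.shape[0]) * dt, c) for c in coords_list]
    return TrajectoryEnsemble(tuple(fibril.atom_names),
                              tuple(fibril.elements), trajs)


class TestRmsf:
    def test_static_trajectory_is_exactly_zero(self, small_fibril):
        coords = np.repeat(small_fibril.coords[None], 5, axis=0)
        ens = _fibril_ensemble(small_fibril, [coords])
        table = rmsf(ens, small_fibril, superpose=False)
        np.testing.assert_array_equal(table.rmsf, 0.0)

    def test_isotropic_jitter_closed_form(self, small_fibril):
        rng = np.random.default_rng(0)
        sigma = 0.05
        coords = small_fibril.coords[None] + rng.normal(
            0, sigma, (2000, small_fibril.n_atoms, 3))
        ens = _fibril_ensemble(small_fibril, [coords])
        table = rmsf(ens, small_fibril, superpose=False)
        expected = sigma * np.sqrt(3)
        np.testing.assert_allclose(table.rmsf, expected, rtol=0.05)

    def test_two_frame_hand_calculation(self, small_fibril):
        # one atom displaced by 0.2 nm between two frames -> RMSF 0.1 nm
        c0 = small_fibril.coords.copy()
        c1 = small_fibril.coords.copy()
        moved = 0  # first atom is an amide N of residue (A, 1)
        c1[moved, 2] += 0.2
        ens = _fibril_ensemble(small_fibril, [np.stack([c0, c1])])
        atom_vals = per_atom_rmsf(np.stack([c0, c1]))
        assert atom_vals[moved] == pytest.approx(0.1, abs=1e-12)
        table = rmsf(ens, small_fibril, superpose=False)
        # residue average over its 4 backbone heavy atoms: 0.1/4
        row = (table.chain_ids == "A") & (table.resids == 1)
        assert table.rmsf[row][0] == pytest.approx(0.1 / 4, abs=1e-12)

    def test_superposition_removes_rigid_body_noise(self, small_fibril):
        from scipy.spatial.transform import Rotation
        rng = np.random.default_rng(1)
        frames = []
        for _ in range(50):
            R = Rotation.from_euler("xyz",
                                    rng.normal(0, 0.05, 3)).as_matrix()
            t = rng.normal(0, 0.05, 3)
            frames.append(small_fibril.coords @ R.T + t)
        ens = _fibril_ensemble(small_fibril, [np.array(frames)])
        fitted = rmsf(ens, small_fibril, superpose=True)
        raw = rmsf(ens, small_fibril, superpose=False)
        assert np.all(fitted.rmsf <= raw.rmsf + 1e-9)
        assert fitted.rmsf.max() < 1e-6  # pure rigid motion fits away

    def test_edge_layers_excluded_from_class_averages(self, small_fibril):
        coords = np.repeat(small_fibril.coords[None], 3, axis=0)
        ens = _fibril_ensemble(small_fibril, [coords])
        table = rmsf(ens, small_fibril, superpose=False,
                     contact_layers={1})
        assert set(table.strand_class[np.isin(table.layer, [0, 3])]) \
            == {"edge"}
        assert set(table.strand_class[table.layer == 1]) == {"contact"}
        assert set(table.strand_class[table.layer == 2]) == {"non_contact"}

    def test_single_frame_warns_and_returns_zero(self, small_fibril):
        ens = _fibril_ensemble(small_fibril, [small_fibril.coords[None]])
        with pytest.warns(UserWarning, match="single-frame"):
            table = rmsf(ens, small_fibril, superpose=False)
        np.testing.assert_array_equal(table.rmsf, 0.0)
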