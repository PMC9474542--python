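"""Contact predicates, polar-bond criteria and contact maps."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from fibrilsite import (ContactCriteria, PolarBondCriteria,
                        contact_probabilities, detect_halogen_bonds,
                        detect_hydrogen_bonds, heavy_atom_contact,
                        nitrogen_backbone_contact)
from fibrilsite.interactions import ligand_protein_hbonds, \
    ligand_protein_xbonds
from fibrilsite.model_io import Trajectory, TrajectoryEnsemble
from tests.conftest import place_ligand_in_cavity


def _pair_at(distance):
    """One ligand atom and one residue atom separated by `distance` nm."""
    lig = np.array([[0.0, 0.0, 0.0]])
    res = np.array([[distance, 0.0, 0.0]])
    return lig, res


class TestHeavyAtomContact:
    def test_below_cutoff_is_contact(self):
        lig, res = _pair_at(0.35)
        formed, n = heavy_atom_contact(lig, ["C"], res, ["O"])
        assert formed and n == 1

    def test_above_cutoff_is_no_contact(self):
        lig, res = _pair_at(0.45)
        formed, n = heavy_atom_contact(lig, ["C"], res, ["O"])
        assert not formed and n == 0

    def test_hydrogens_ignored(self):
        lig = np.array([[0.0, 0.0, 0.0], [0.3, 0.0, 0.0]])
        res = np.array([[0.35, 0.0, 0.0]])
        # the close ligand atom is a hydrogen; the carbon is at 0.35
        formed, n = heavy_atom_contact(lig, ["C", "H"], res, ["O"])
        assert formed and n == 1

    def test_matches_brute_force_on_random_frames(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n_lig = rng.integers(5, 30)
            n_res = rng.integers(5, 30)
            lig = rng.uniform(0, 1.5, (n_lig, 3))
            res = rng.uniform(0, 1.5, (n_res, 3))
            lig_el = rng.choice(["C", "N", "O", "H"], n_lig)
            res_el = rng.choice(["C", "N", "O", "H"], n_res)
            formed, n = heavy_atom_contact(lig, lig_el, res, res_el)
            d = cdist(lig[lig_el != "H"], res[res_el != "H"])
            assert formed == bool((d <= 0.40).any())
            assert n == int((d.min(axis=1) <= 0.40).sum())


class TestNitrogenBackboneContact:
    def test_backbone_ca_within_cutoff(self, ligand):
        coords = ligand.reference_coords.copy()
        n1 = coords[ligand.index_of("N1")]
        res = np.array([n1 + [0.49, 0, 0]])
        assert nitrogen_backbone_contact(coords, ligand, res, ["CA"])

    def test_sidechain_atom_does_not_count(self, ligand):
        coords = ligand.reference_coords.copy()
        n1 = coords[ligand.index_of("N1")]
        res = np.array([n1 + [0.49, 0, 0]])
        assert not nitrogen_backbone_contact(coords, ligand, res, ["CB"])

    def test_ca_flag_restricts_to_c_and_n(self, ligand):
        coords = ligand.reference_coords.copy()
        n1 = coords[ligand.index_of("N1")]
        res = np.array([n1 + [0.49, 0, 0]])
        assert not nitrogen_backbone_contact(coords, ligand, res, ["CA"],
                                             include_ca=False)

    def test_matches_brute_force_on_random_frames(self, ligand):
        rng = np.random.default_rng(7)
        n_idx = ligand.group_indices("pyrazole_N")
        for _ in range(100):
            coords = rng.uniform(0, 1.2, (ligand.n_atoms, 3))
            n_res = rng.integers(3, 12)
            res = rng.uniform(0, 1.2, (n_res, 3))
            names = rng.choice(["N", "C", "CA", "CB", "O"], n_res)
            got = nitrogen_backbone_contact(coords, ligand, res, names)
            bb = np.isin(names, ["N", "C", "CA"])
            want = bool(bb.any() and
                        (cdist(coords[n_idx], res[bb]) <= 0.50).any())
            assert got == want


class TestHydrogenBonds:
    def test_linear_short_bond_formed(self):
        d = np.array([0, 0, 0.0])
        h = np.array([0, 0, 0.10])
        a = np.array([0, 0, 0.30])
        bonds = detect_hydrogen_bonds([(d, h, "N")], [(a, "O")])
        assert len(bonds) == 1
        assert bonds[0].angle == pytest.approx(180.0)
        assert bonds[0].energy < 0

    def test_bent_geometry_rejected(self):
        d = np.array([0, 0, 0.0])
        h = np.array([0, 0, 0.10])
        # acceptor placed so that the D-H...A angle is 120 degrees
        a = h + 0.25 * np.array([np.sin(np.deg2rad(60)), 0,
                                 np.cos(np.deg2rad(60))])
        assert np.linalg.norm(a - d) < 0.35
        assert detect_hydrogen_bonds([(d, h, "N")], [(a, "O")]) == []

    def test_donor_without_hydrogen_is_error(self):
        with pytest.raises(ValueError, match="no attached hydrogen"):
            detect_hydrogen_bonds([(np.zeros(3), None, "N")],
                                  [(np.ones(3), "O")])

    def test_grid_matches_direct_inequalities(self):
        rng = np.random.default_rng(11)
        criteria = PolarBondCriteria()
        d = np.zeros(3)
        h = np.array([0, 0, 0.10])
        for _ in range(1000):
            r = rng.uniform(0.25, 0.45)
            theta = rng.uniform(100.0, 180.0)
            # place A so that |D-A| = r and the D-H...A angle is theta
            ct = np.cos(np.deg2rad(theta))
            s = 0.1 * ct + np.sqrt(r ** 2 - 0.01 * (1 - ct ** 2))
            u = np.array([np.sin(np.deg2rad(180 - theta)), 0,
                          np.cos(np.deg2rad(180 - theta))])
            a = h + s * u
            got = bool(detect_hydrogen_bonds([(d, h, "N")], [(a, "O")],
                                             criteria))
            want = (r <= criteria.hb_donor_acceptor_cutoff
                    and theta >= criteria.hb_angle_min)
            assert got == want


class TestHalogenBonds:
    @pytest.mark.parametrize("dist, angle, expected", [
        (0.35, 165.0, True),    # both criteria met
        (0.35, 140.0, False),   # angle fails
        (0.37, 179.0, False),   # distance fails
    ])
    def test_printed_examples(self, dist, angle, expected):
        c = np.zeros(3)
        x = np.array([0, 0, 0.19])
        u = np.array([np.sin(np.deg2rad(180 - angle)), 0,
                      np.cos(np.deg2rad(180 - angle))])
        o = x + dist * u
        bonds = detect_halogen_bonds(x, c, [(o, "O")])
        assert bool(bonds) == expected

    def test_grid_matches_direct_inequalities(self):
        rng = np.random.default_rng(13)
        criteria = PolarBondCriteria()
        c = np.zeros(3)
        x = np.array([0, 0, 0.19])
        for _ in range(1000):
            r = rng.uniform(0.30, 0.42)
            theta = rng.uniform(120.0, 180.0)
            u = np.array([np.sin(np.deg2rad(180 - theta)), 0,
                          np.cos(np.deg2rad(180 - theta))])
            o = x + r * u
            got = bool(detect_halogen_bonds(x, c, [(o, "O")], criteria))
            want = (r <= criteria.xb_distance_cutoff
                    and theta >= criteria.xb_angle_min)
            assert got == want


class TestContactMonotonicity:
    def test_contact_set_grows_with_cutoff(self):
        rng = np.random.default_rng(3)
        lig = rng.uniform(0, 1.0, (10, 3))
        res = rng.uniform(0, 1.0, (10, 3))
        els = ["C"] * 10
        _, n_small = heavy_atom_contact(lig, els, res, els, cutoff=0.3)
        _, n_large = heavy_atom_contact(lig, els, res, els, cutoff=0.5)
        assert n_large >= n_small

    def test_symmetric_in_the_two_atom_sets(self):
        rng = np.random.default_rng(5)
        a = rng.uniform(0, 1.0, (8, 3))
        b = rng.uniform(0, 1.0, (12, 3))
        ea, eb = ["C"] * 8, ["O"] * 12
        assert heavy_atom_contact(a, ea, b, eb)[0] \
            == heavy_atom_contact(b, eb, a, ea)[0]


class TestContactProbabilities:
    def _ensemble(self, ligand, frames):
        return TrajectoryEnsemble(
            tuple(ligand.atom_names), tuple(ligand.elements),
            [Trajectory(np.arange(len(f)) * 0.1, np.array(f))
             for f in frames])

    def test_welded_contact_probability_one(self, ligand, fibril):
        frame = place_ligand_in_cavity(ligand, fibril, z=2.2)
        ens = self._ensemble(ligand, [[frame] * 4])
        cmap = contact_probabilities(ens, fibril, ligand, definition="heavy")
        probs = cmap[cmap["atom_kind"] == "any"]["probability"]
        assert probs.max() == pytest.approx(1.0)

    def test_quarter_occupancy(self, ligand, fibril):
        near = place_ligand_in_cavity(ligand, fibril, z=2.2)
        far = near + np.array([50.0, 0, 0])
        ens = self._ensemble(ligand, [[near, far, far, far]])
        cmap = contact_probabilities(ens, fibril, ligand, definition="heavy")
        assert cmap["probability"].max() == pytest.approx(0.25)

    def test_trajectory_mean_of_means(self, ligand, fibril):
        near = place_ligand_in_cavity(ligand, fibril, z=2.2)
        far = near + np.array([50.0, 0, 0])
        # per-trajectory means 0.2 and 0.6 -> ensemble probability 0.4
        t1 = [near] + [far] * 4            # 1/5 = 0.2
        t2 = [near, near, near, far, far]  # 3/5 = 0.6
        ens = self._ensemble(ligand, [t1, t2])
        cmap = contact_probabilities(ens, fibril, ligand, definition="heavy")
        assert cmap["probability"].max() == pytest.approx(0.4)

    def test_edge_layers_excluded(self, ligand, fibril):
        frame = place_ligand_in_cavity(ligand, fibril, z=2.2)
        ens = self._ensemble(ligand, [[frame]])
        incl = contact_probabilities(
            ens, fibril, ligand,
            ContactCriteria(exclude_edge_layers=False), "heavy")
        excl = contact_probabilities(
            ens, fibril, ligand,
            ContactCriteria(exclude_edge_layers=True), "heavy")
        assert excl["residue"].size < incl["residue"].size
        assert set(excl["layer"]) <= set(range(1, 9))

    def test_probabilities_within_unit_interval(self, ligand, fibril,
                                                hopping_run):
        _, ens, _ = hopping_run
        from fibrilsite.model_io import Trajectory, TrajectoryEnsemble
        short = TrajectoryEnsemble(
            ens.atom_names, ens.elements,
            [Trajectory(t.times[:50], t.coords[:50])
             for t in ens.trajectories])
        for definition in ("heavy", "nitrogen_backbone"):
            cmap = contact_probabilities(short, fibril, ligand,
                                         definition=definition)
            assert (cmap["probability"] >= 0).all()
            assert (cmap["probability"] <= 1).all()


class TestLigandProteinBonds:
    def test_pyrazole_donor_bond_found(self, ligand, fibril):
        # put the ligand N1-H right next to a backbone carbonyl O
        o_idx = np.where((fibril.atom_names == "O")
                         & (fibril.layer_index == 2))[0][0]
        o_xyz = fibril.coords[o_idx]
        n1 = ligand.index_of("N1")
        hn1 = ligand.index_of("HN1")
        coords = ligand.reference_coords.copy()
        nh = coords[hn1] - coords[n1]
        nh /= np.linalg.norm(nh)
        # N1 placed 0.30 nm from O, N-H pointing straight at it
        coords = coords - coords[n1] + o_xyz - 0.30 * nh
        bonds = ligand_protein_hbonds(coords, ligand, fibril)
        assert any(b.ligand_group == "pyrazole" and b.protein_atom == "O"
                   for b in bonds)

    def test_halogen_bond_found_with_aligned_geometry(self, ligand, fibril):
        o_idx = np.where((fibril.atom_names == "O")
                         & (fibril.layer_index == 2))[0][0]
        o_xyz = fibril.coords[o_idx]
        br = ligand.index_of("BR")
        c = ligand.index_of("C3P")
        coords = ligand.reference_coords.copy()
        cb = coords[br] - coords[c]
        cb /= np.linalg.norm(cb)
        # Br 0.33 nm from O along the C-Br direction (C-Br...O = 180 deg)
        coords = coords - coords[br] + o_xyz - 0.33 * cb
        bonds = ligand_protein_xbonds(coords, ligand, fibril)
        assert len(bonds) >= 1
        assert all(b.angle >= 150.0 and b.distance <= 0.36 for b in bonds)
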