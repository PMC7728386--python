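"""Structure input, property assignment, mutation centers, superposition."""

import logging

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from voxstab.chem import CHANNEL_NAMES, PropertyRuleSet
from voxstab.fixtures import FixtureConfig, make_structure_pair, to_pdb_text
from voxstab.structures import (
    PDBParseError,
    assign_properties,
    mutation_center,
    read_pdb,
    superpose,
)

from conftest import make_point_structure

CH = {name: i for i, name in enumerate(CHANNEL_NAMES)}

FIVE_ATOM_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      12.633   7.208  -4.922  1.00  0.00           C
ATOM      4  O   ALA A   1      13.807   7.113  -5.288  1.00  0.00           O
ATOM      5  CB  ALA A   1      12.321   4.719  -4.899  1.00  0.00           C
END
"""

WATER_ONLY_PDB = """\
HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O
HETATM    2  O   HOH A   2       3.000   0.000   0.000  1.00  0.00           O
END
"""


class TestReadPdb:
    def test_atom_count_preserved(self, tmp_path):
        path = tmp_path / "five.pdb"
        path.write_text(FIVE_ATOM_PDB)
        model = read_pdb(path)
        assert model.n_atoms == 5
        assert model.chains() == ["A"]
        np.testing.assert_allclose(model.coord[0], [11.104, 6.134, -6.504])

    def test_model_selection_matches_line_filter(self, tmp_path):
        # two MODEL blocks with different coordinates
        block1 = FIVE_ATOM_PDB.replace("END\n", "")
        block2 = block1.replace("11.104", "99.000")
        text = f"MODEL        1\n{block1}ENDMDL\nMODEL        2\n{block2}ENDMDL\nEND\n"
        path = tmp_path / "multi.pdb"
        path.write_text(text)
        model = read_pdb(path, model_index=1)
        # independent line-filtering oracle: coordinates of the first block
        expected = []
        in_model = False
        for line in text.splitlines():
            if line.startswith("MODEL") and line.split()[1] == "1":
                in_model = True
            elif line.startswith("ENDMDL"):
                in_model = False
            elif in_model and line.startswith("ATOM"):
                expected.append([float(line[30:38]), float(line[38:46]),
                                 float(line[46:54])])
        np.testing.assert_allclose(model.coord, expected)
        assert model.n_atoms == 5

    def test_water_only_file_rejected(self, tmp_path):
        path = tmp_path / "hoh.pdb"
        path.write_text(WATER_ONLY_PDB)
        with pytest.raises(PDBParseError, match="no protein atoms"):
            read_pdb(path)


@pytest.fixture(scope="module")
def helix():
    wt, _ = make_structure_pair("L", "A", 10, FixtureConfig(n_mutations=1, seed=0))
    return assign_properties(wt)


@pytest.fixture(scope="module")
def gly_pair():
    return make_structure_pair("L", "G", 10, FixtureConfig(n_mutations=1, seed=0))


class TestAssignProperties:
    def _atom_flags(self, model, res_name, atom_name):
        idx = np.flatnonzero((model.res_name == res_name) & (model.atom_name == atom_name))
        assert idx.size > 0, f"{res_name} {atom_name} not found"
        return model.flags[idx[0]]

    def test_ala_cb_is_aliphatic_carbon(self, helix):
        f = self._atom_flags(helix, "ALA", "CB")
        assert f[CH["hydrophobic"]] and not f[CH["aromatic"]]
        assert f[CH["occupancy"]]
        assert not any(f[CH[c]] for c in ("donor", "acceptor", "positive", "negative"))

    def test_phe_ring_carbon_is_aromatic_and_hydrophobic(self, helix):
        f = self._atom_flags(helix, "PHE", "CZ")
        assert f[CH["aromatic"]] and f[CH["hydrophobic"]]

    def test_lys_nz_is_positive_and_lone_pair_donor(self, helix):
        f = self._atom_flags(helix, "LYS", "NZ")
        assert f[CH["positive"]] and f[CH["donor"]]

    def test_polar_hydrogens_flagged_and_carbon_hydrogens_not(self, helix):
        # Ser OG hydrogen is polar; Ala CB hydrogens are not
        assert self._atom_flags(helix, "SER", "HG")[CH["acceptor"]]
        assert not self._atom_flags(helix, "ALA", "HB1")[CH["acceptor"]]

    def test_asp_carboxylate_negative_not_hydrophobic(self, helix):
        assert self._atom_flags(helix, "ASP", "OD1")[CH["negative"]]
        assert not self._atom_flags(helix, "ASP", "CG")[CH["hydrophobic"]]

    def test_structure_without_hydrogens_has_empty_acceptor_channel(self, caplog):
        wt, _ = make_structure_pair("L", "A", 10, FixtureConfig(n_mutations=1, seed=0))
        heavy = np.flatnonzero(wt.element != "H")
        stripped = wt.copy()
        for attr in ("serial", "atom_name", "element", "res_name", "res_id",
                     "ins_code", "chain_id"):
            setattr(stripped, attr, getattr(stripped, attr)[heavy])
        stripped.coord = stripped.coord[heavy]
        with caplog.at_level(logging.WARNING):
            out = assign_properties(stripped)
        assert not out.flags[:, CH["acceptor"]].any()
        assert any("no hydrogens" in rec.message for rec in caplog.records)

    def test_invariants_and_idempotence(self, helix):
        assert helix.flags[:, CH["occupancy"]].all()
        aromatic = helix.flags[:, CH["aromatic"]]
        assert helix.flags[aromatic, CH["hydrophobic"]].all()
        again = assign_properties(helix)
        np.testing.assert_array_equal(again.flags, helix.flags)

    def test_donor_acceptor_swap_switch(self, helix):
        wt, _ = make_structure_pair("L", "A", 10, FixtureConfig(n_mutations=1, seed=0))
        swapped = assign_properties(wt, PropertyRuleSet(swap_donor_acceptor=True))
        np.testing.assert_array_equal(
            swapped.flags[:, CH["donor"]], helix.flags[:, CH["acceptor"]])
        np.testing.assert_array_equal(
            swapped.flags[:, CH["acceptor"]], helix.flags[:, CH["donor"]])


class TestMutationCenter:
    def test_returns_cb_for_leucine(self, gly_pair):
        wt, _ = gly_pair
        cb = wt.atom_coord("A", 10, "CB")
        np.testing.assert_allclose(mutation_center(wt, "A", 10), cb)

    def test_returns_ca_for_glycine(self, gly_pair):
        _, mut = gly_pair
        ca = mut.atom_coord("A", 10, "CA")
        np.testing.assert_allclose(mutation_center(mut, "A", 10), ca)

    def test_missing_chain_is_an_error(self, gly_pair):
        with pytest.raises(KeyError, match="Z:10"):
            mutation_center(gly_pair[0], "Z", 10)


def _brute_force_rmsd(mobile, reference, n_grid=14):
    """Independent oracle: minimize anchor RMSD over sampled rotations."""
    mob = mobile - mobile.mean(axis=0)
    ref = reference - reference.mean(axis=0)

    def rmsd_of(rotvec):
        rot = Rotation.from_rotvec(rotvec)
        return np.sqrt(np.mean(np.sum((rot.apply(mob) - ref) ** 2, axis=1)))

    angles = np.linspace(-np.pi, np.pi, n_grid, endpoint=False)
    best, best_val = None, np.inf
    for ax in angles:
        for ay in angles:
            for az in angles:
                vec = Rotation.from_euler("xyz", [ax, ay, az]).as_rotvec()
                val = rmsd_of(vec)
                if val < best_val:
                    best, best_val = vec, val
    res = minimize(rmsd_of, best, method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
    return float(res.fun)


class TestSuperpose:
    def _structures(self, coords_mobile, coords_ref):
        return (make_point_structure(coords_mobile, structure_id="mob"),
                make_point_structure(coords_ref, structure_id="ref"))

    def test_identity_is_a_fixed_point(self):
        coords = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0.3, 0.4, 1.1]])
        mob, ref = self._structures(coords, coords)
        fit, rmsd = superpose(mob, ref)
        assert rmsd == pytest.approx(0.0, abs=1e-6)
        np.testing.assert_allclose(fit.coord, coords, atol=1e-6)

    def test_recovers_exact_rigid_motion(self):
        rng = np.random.default_rng(0)
        ref_coords = rng.normal(size=(6, 3))
        rot = Rotation.from_euler("z", np.pi / 2)
        mob_coords = rot.apply(ref_coords) + np.array([5.0, -2.0, 1.0])
        mob, ref = self._structures(mob_coords, ref_coords)
        fit, rmsd = superpose(mob, ref)
        assert rmsd <= 1e-6
        np.testing.assert_allclose(fit.coord, ref_coords, atol=1e-6)

    def test_noisy_four_point_fit_matches_brute_force(self):
        rng = np.random.default_rng(3)
        ref_coords = np.array([[0.0, 0, 0], [2, 0, 0], [0, 3, 0], [1, 1, 2.5]])
        rot = Rotation.from_euler("xyz", [0.4, -0.8, 1.9])
        mob_coords = rot.apply(ref_coords) + rng.normal(0, 0.1, size=(4, 3)) + 3.0
        mob, ref = self._structures(mob_coords, ref_coords)
        _, rmsd = superpose(mob, ref)
        oracle = _brute_force_rmsd(mob_coords, ref_coords)
        assert rmsd == pytest.approx(oracle, abs=1e-3)

    def test_never_increases_anchor_rmsd(self):
        rng = np.random.default_rng(7)
        for trial in range(5):
            ref_coords = rng.normal(size=(5, 3)) * 3
            mob_coords = ref_coords + rng.normal(0, 0.5, size=(5, 3))
            mob, ref = self._structures(mob_coords, ref_coords)
            before = np.sqrt(np.mean(np.sum((mob_coords - ref_coords) ** 2, axis=1)))
            _, after = superpose(mob, ref)
            assert after <= before + 1e-12

    def test_invariant_under_rigid_pretransform(self):
        rng = np.random.default_rng(11)
        ref_coords = rng.normal(size=(5, 3)) * 2
        mob_coords = ref_coords + rng.normal(0, 0.2, size=(5, 3))
        mob, ref = self._structures(mob_coords, ref_coords)
        fit1, rmsd1 = superpose(mob, ref)
        pre = Rotation.from_euler("xyz", [1.0, 0.5, -2.0])
        mob2, _ = self._structures(pre.apply(mob_coords) + 7.0, ref_coords)
        fit2, rmsd2 = superpose(mob2, ref)
        assert rmsd2 == pytest.approx(rmsd1, abs=1e-6)
        np.testing.assert_allclose(fit2.coord, fit1.coord, atol=1e-6)

    def test_too_few_anchors_rejected(self):
        mob, ref = self._structures(np.zeros((2, 3)), np.zeros((2, 3)))
        with pytest.raises(ValueError, match=">= 3"):
            superpose(mob, ref)

    def test_mutation_site_excluded_from_anchors(self):
        coords = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0], [0, 0, 1]])
        mob_coords = coords.copy()
        mob_coords[2] += 10.0  # displaced residue 3: excluded from the fit
        mob, ref = self._structures(mob_coords, coords)
        _, rmsd_excl = superpose(mob, ref, exclude_site=("A", 3))
        assert rmsd_excl == pytest.approx(0.0, abs=1e-9)


def test_generated_pdb_round_trips(tmp_path):
    wt, mut = make_structure_pair("V", "A", 10, FixtureConfig(n_mutations=1, seed=5))
    path = tmp_path / "wt.pdb"
    path.write_text(to_pdb_text(wt))
    parsed = read_pdb(path)
    assert parsed.n_atoms == wt.n_atoms
    np.testing.assert_allclose(parsed.coord, wt.coord, atol=1e-3)  # PDB precision
    assert parsed.chain_sequence("A") == wt.chain_sequence("A")
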