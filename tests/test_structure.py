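"""Structure module: parsing, contact criteria, superposition, B-factors."""

import numpy as np
import pytest
from scipy.optimize import minimize

from covkin.structure import (
    bfactor_profile,
    find_hbond_candidates,
    find_nonpolar_contacts,
    kabsch,
    ligand_rmsd,
    structure_from_pdb_string,
    superpose_backbone,
)
from toystructures import (
    build_pdb,
    contact_complex_pdb,
    ligand_complex_pdb,
    pdb_line,
    protein_only_pdb,
    random_rotation,
    rigid_transform,
    backbone_atoms,
)


def brute_force_superposition_rmsd(moving, fixed, n_starts=60, seed=0):
    """Independent oracle: numerical minimisation over rotation angles.

    Parametrises the rotation by Euler angles (translation solved per
    rotation via centroids) and polishes from many random starts.
    """
    moving = np.asarray(moving, float)
    fixed = np.asarray(fixed, float)
    mc, fc = moving.mean(0), fixed.mean(0)
    a, b = moving - mc, fixed - fc

    def rot(angles):
        ca, cb_, cc = np.cos(angles)
        sa, sb, sc = np.sin(angles)
        rx = np.array([[1, 0, 0], [0, ca, -sa], [0, sa, ca]])
        ry = np.array([[cb_, 0, sb], [0, 1, 0], [-sb, 0, cb_]])
        rz = np.array([[cc, -sc, 0], [sc, cc, 0], [0, 0, 1]])
        return rz @ ry @ rx

    def objective(angles):
        d = a @ rot(angles).T - b
        return float(np.mean(np.sum(d * d, axis=1)))

    rng = np.random.default_rng(seed)
    best = np.inf
    for _ in range(n_starts):
        x0 = rng.uniform(-np.pi, np.pi, 3)
        res = minimize(objective, x0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 2000})
        best = min(best, res.fun)
    return float(np.sqrt(best))


class TestParsing:
    def test_three_atom_toy_exact_coordinates(self):
        text = build_pdb([
            ("N", "GLY", "A", 1, (1.0, 2.0, 3.0), 1.0, 10.0, "N", False),
            ("CA", "GLY", "A", 1, (2.5, 2.0, 3.0), 1.0, 11.0, "C", False),
            ("C", "GLY", "A", 1, (3.1, 3.2, 3.0), 1.0, 12.0, "C", False),
        ])
        model = structure_from_pdb_string(text)
        assert len(model.atoms) == 3
        np.testing.assert_allclose(model.atoms[0].pos, [1.0, 2.0, 3.0])
        assert model.atoms[1].name == "CA"
        assert model.atoms[2].bfactor == pytest.approx(12.0)

    def test_altloc_highest_occupancy_retained(self):
        lines = [
            pdb_line(1, "CA", "GLY", "A", 1, (0, 0, 0), occ=0.4, element="C",
                     altloc="A"),
            pdb_line(2, "CA", "GLY", "A", 1, (5, 0, 0), occ=0.6, element="C",
                     altloc="B"),
        ]
        model = structure_from_pdb_string("\n".join(lines + ["END"]) + "\n")
        assert len(model.atoms) == 1
        np.testing.assert_allclose(model.atoms[0].pos, [5, 0, 0])
        assert model.atoms[0].altloc == "B"

    def test_empty_file_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            structure_from_pdb_string("")

    def test_malformed_coordinates_reported_with_line_number(self):
        good = pdb_line(1, "CA", "GLY", "A", 1, (0, 0, 0))
        bad = good[:30] + "  xx.xxx" + good[38:]
        with pytest.raises(ValueError, match=r"lines \[2\]"):
            structure_from_pdb_string(good + "\n" + bad + "\nEND\n")


@pytest.fixture(scope="module")
def model():
    return structure_from_pdb_string(contact_complex_pdb())


class TestContacts:
    def test_hbond_candidate_within_cutoff(self, model):
        records = find_hbond_candidates(model, "LIG")
        pairs = {(r.protein_atom.name, r.ligand_atom.name) for r in records}
        assert ("N", "O1") in pairs
        assert all(r.distance <= 3.3 for r in records)

    def test_pair_just_outside_cutoff_excluded(self, model):
        records = find_hbond_candidates(model, "LIG")
        assert not any(r.ligand_atom.name == "O2" for r in records)

    def test_covalent_adduct_linkage_excluded(self, model):
        # SG-S1 at 2.05 Å is a covalent bond, not a hydrogen bond
        records = find_hbond_candidates(model, "LIG")
        assert not any(r.ligand_atom.name == "S1" for r in records)

    def test_hydrophobic_pair_detected(self, model):
        records = find_nonpolar_contacts(model, "LIG")
        pairs = {(r.protein_atom.name, r.ligand_atom.name) for r in records}
        assert ("CB", "CM1") in pairs

    def test_carbonyl_carbon_not_hydrophobic(self, model):
        records = find_nonpolar_contacts(model, "LIG")
        assert not any(r.protein_atom.name == "C" for r in records)
        assert not any(r.ligand_atom.name == "CM2" for r in records)

    def test_pair_beyond_contact_cutoff_excluded(self, model):
        records = find_nonpolar_contacts(model, "LIG")
        assert not any(r.ligand_atom.name == "CM3" for r in records)

    def test_empty_ligand_selection_raises(self, model):
        with pytest.raises(ValueError, match="selection"):
            find_hbond_candidates(model, "XYZ")

    def test_hbond_candidates_within_generic_contact_cutoff(self, model):
        assert all(r.distance <= 4.2 for r in find_hbond_candidates(model, "LIG"))

    def test_invariant_under_rigid_motion(self, model):
        rot = random_rotation(3)
        trans = np.array([11.0, -4.0, 2.5])
        moved = model.transformed(rot, trans)
        for finder in (find_hbond_candidates, find_nonpolar_contacts):
            orig = finder(model, "LIG")
            new = finder(moved, "LIG")
            assert [(r.protein_atom.name, r.ligand_atom.name) for r in orig] == \
                [(r.protein_atom.name, r.ligand_atom.name) for r in new]
            np.testing.assert_allclose([r.distance for r in orig],
                                       [r.distance for r in new], atol=1e-9)


class TestSuperposition:
    def test_self_superposition_zero_rmsd(self):
        m = structure_from_pdb_string(protein_only_pdb())
        sup = superpose_backbone(m, m)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        assert sup.n_atoms_matched == 15

    def test_rigid_copy_zero_rmsd_and_proper_rotation(self):
        m = structure_from_pdb_string(protein_only_pdb())
        moved = m.transformed(random_rotation(1), np.array([3.0, -7.0, 12.0]))
        sup = superpose_backbone(moved, m)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-6)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-6)
        assert np.allclose(sup.rotation @ sup.rotation.T, np.eye(3), atol=1e-9)

    def test_displaced_atom_rmsd_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        fixed = rng.normal(size=(4, 3)) * 3.0
        moving = fixed.copy()
        moving[2] += np.array([1.0, 0.0, 0.0])  # one atom displaced by 1 Å
        moving = moving @ random_rotation(8).T + np.array([2.0, 2.0, -1.0])
        analytic = kabsch(moving, fixed).rmsd
        oracle = brute_force_superposition_rmsd(moving, fixed)
        assert analytic == pytest.approx(oracle, abs=1e-3)
        # Kabsch is the global optimum: never above the oracle's best
        assert analytic <= oracle + 1e-6

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_toys_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        fixed = rng.normal(size=(8, 3)) * 4.0
        moving = fixed + rng.normal(size=(8, 3)) * 0.5
        analytic = kabsch(moving, fixed).rmsd
        oracle = brute_force_superposition_rmsd(moving, fixed, n_starts=40,
                                                seed=seed)
        assert analytic == pytest.approx(oracle, abs=1e-3)

    def test_insufficient_overlap_raises(self):
        a = structure_from_pdb_string(protein_only_pdb())
        b_atoms = backbone_atoms(2)
        b = structure_from_pdb_string(build_pdb(b_atoms))
        with pytest.raises(ValueError, match="overlap"):
            superpose_backbone(a, b)


class TestLigandRMSD:
    def test_identical_complexes_zero(self):
        a = structure_from_pdb_string(ligand_complex_pdb())
        b = structure_from_pdb_string(ligand_complex_pdb())
        assert ligand_rmsd(a, b, "LIG") == pytest.approx(0.0, abs=1e-9)

    def test_translated_ligand_in_fixed_frame(self):
        a = structure_from_pdb_string(ligand_complex_pdb(ligand_shift=(1, 0, 0)))
        b = structure_from_pdb_string(ligand_complex_pdb())
        assert ligand_rmsd(a, b, "LIG") == pytest.approx(1.0, abs=1e-6)

    def test_known_displacement_field_hand_computed(self):
        # per-atom displacements 0.2, 0.4, 0.6, 0.8 Å along z:
        # rms = sqrt(mean(d^2)) = sqrt(0.3) = 0.5477...
        import toystructures as toys
        rng = np.random.default_rng(42)
        atoms = toys.backbone_atoms(5, rng=rng)
        lig_a, lig_b = [], []
        for i, d in enumerate([0.2, 0.4, 0.6, 0.8]):
            base = np.array([2.0 + i, 5.0, 2.0])
            lig_a.append((f"C{i}", "LIG", "L", 200, base + [0, 0, d],
                          1.0, 20.0, "C", True))
            lig_b.append((f"C{i}", "LIG", "L", 200, base, 1.0, 20.0, "C", True))
        a = structure_from_pdb_string(toys.build_pdb(atoms + lig_a))
        b = structure_from_pdb_string(toys.build_pdb(atoms + lig_b))
        expected = np.sqrt(np.mean(np.square([0.2, 0.4, 0.6, 0.8])))
        assert ligand_rmsd(a, b, "LIG") == pytest.approx(expected, abs=1e-9)

    def test_atom_name_mismatch_raises(self):
        a = structure_from_pdb_string(ligand_complex_pdb())
        text = ligand_complex_pdb().replace("C2  ", "C9  ")
        b = structure_from_pdb_string(text)
        with pytest.raises(ValueError, match="mismatch"):
            ligand_rmsd(a, b, "LIG")


class TestBfactorProfile:
    def test_uniform_b_flags_first_by_name(self):
        m = structure_from_pdb_string(ligand_complex_pdb())
        table, max_atom = bfactor_profile(m, "LIG")
        assert max_atom == "C1"  # alphabetical order decides ties
        assert table["bfactor"].max() - table["bfactor"].min() == pytest.approx(0.0)

    def test_hot_atom_flagged(self):
        m = structure_from_pdb_string(
            ligand_complex_pdb(ligand_b=[20.0, 80.0, 20.0, 20.0]))
        table, max_atom = bfactor_profile(m, "LIG")
        assert max_atom == "C2"
        assert table.loc[table["is_max"], "bfactor"].iloc[0] == pytest.approx(80.0)

    def test_substructure_means(self):
        m = structure_from_pdb_string(
            ligand_complex_pdb(ligand_b=[10.0, 20.0, 30.0, 40.0]))
        table, _, means = bfactor_profile(
            m, "LIG", substructures={"scaffold": ["C1", "C2"],
                                     "warhead": ["N1", "O1"]})
        assert means["scaffold"] == pytest.approx(15.0)
        assert means["warhead"] == pytest.approx(35.0)
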