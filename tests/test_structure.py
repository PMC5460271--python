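"""Structure parsing, SASA, residue classification and contact detection."""

import math

import numpy as np
import pytest

from lectnet.structure import (
    Atom,
    SasaProfile,
    Structure,
    StructureError,
    atom_sasa,
    classify_residues,
    compute_sasa,
    find_interface_pairs,
    find_ligand_contacts,
    load_sasa_tables,
    read_structure,
)

from conftest import single_atom_structure


class TestReadStructure:
    def test_minimal_two_atom_parse(self, two_atom_pdb):
        s = read_structure(two_atom_pdb)
        assert s.n_atoms == 2
        assert s.atoms[0].residue == ("A", 1, "ALA")
        assert np.allclose(s.xyz()[0], [11.104, 6.134, -6.504])

    def test_waters_only_is_empty_selection(self, water_only_pdb):
        with pytest.raises(StructureError, match="empty selection"):
            read_structure(water_only_pdb)

    def test_malformed_coordinate_raises(self, two_atom_pdb):
        bad = two_atom_pdb.replace("11.104", "xx.104")
        with pytest.raises(StructureError):
            read_structure(bad)

    def test_hydrogens_dropped_ligand_flagged(self):
        text = (
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  H   ALA A   1       1.000   0.000   0.000  1.00  0.00           H\n"
            "HETATM    3  C1  MAN A 201       5.000   0.000   0.000  1.00  0.00           C\n"
            "END\n"
        )
        s = read_structure(text)
        assert s.n_atoms == 2
        assert [a.is_hetero for a in s.atoms] == [False, True]


class TestSasa:
    def test_isolated_carbon_matches_analytic_sphere(self):
        s = single_atom_structure("C")
        profile = compute_sasa(s, probe=1.4, n_points=960)
        expected = 4.0 * math.pi * (1.7 + 1.4) ** 2  # ~120.76 A^2
        assert profile.absolute[0] == pytest.approx(expected, rel=1e-12)

    def test_caged_atom_has_zero_sasa(self):
        # 26 neighbours on a tight cubic shell occlude the centre completely
        offsets = [
            np.array([i, j, k], dtype=float)
            for i in (-1, 0, 1)
            for j in (-1, 0, 1)
            for k in (-1, 0, 1)
            if (i, j, k) != (0, 0, 0)
        ]
        coords = [np.zeros(3)] + [2.0 * o / np.linalg.norm(o) for o in offsets]
        radii = np.full(len(coords), 1.7)
        areas = atom_sasa(np.array(coords), radii, probe=1.4)
        assert areas[0] == 0.0

    def test_overlapping_pair_matches_high_density_oracle(self):
        coords = np.array([[0.0, 0.0, 0.0], [2.5, 0.0, 0.0]])
        radii = np.array([1.7, 1.52])
        fast = atom_sasa(coords, radii, probe=1.4, n_points=960)
        dense = atom_sasa(coords, radii, probe=1.4, n_points=10000)
        assert np.all(np.abs(fast - dense) / dense < 0.02)

    def test_total_area_matches_biotite(self):
        import biotite.structure as bs

        rng = np.random.default_rng(7)
        coords = rng.uniform(0, 12, (25, 3))
        mine = atom_sasa(coords, np.full(25, 1.7), probe=1.4, n_points=960)
        arr = bs.AtomArray(25)
        arr.coord = coords.astype(np.float32)
        arr.element = np.array(["C"] * 25)
        ref = bs.sasa(arr, probe_radius=1.4, point_number=2000, vdw_radii=np.full(25, 1.7))
        assert mine.sum() == pytest.approx(ref.sum(), rel=0.02)

    def test_sasa_monotone_under_added_neighbors(self):
        base = np.zeros((1, 3))
        radii1 = np.array([1.7])
        area0 = atom_sasa(base, radii1)[0]
        prev = area0
        rng = np.random.default_rng(3)
        coords = [np.zeros(3)]
        for _ in range(6):
            u = rng.normal(size=3)
            coords.append(3.0 * u / np.linalg.norm(u))
            areas = atom_sasa(np.array(coords), np.full(len(coords), 1.7))
            assert areas[0] <= prev + 1e-9
            assert areas[0] <= area0
            prev = areas[0]

    def test_unknown_element_raises(self):
        s = single_atom_structure("XX")
        with pytest.raises(StructureError, match="radius"):
            compute_sasa(s)

    def test_relative_sasa_uses_reference_table(self):
        s = single_atom_structure("C")
        profile = compute_sasa(s)
        _, max_table = load_sasa_tables()
        assert profile.relative[0] == pytest.approx(profile.absolute[0] / max_table["ALA"])


def _profile(values: dict) -> SasaProfile:
    residues = list(values)
    rel = np.array([values[r] for r in residues])
    return SasaProfile(residues, rel * 100.0, rel)


class TestClassification:
    def test_definition_cases(self):
        mono = _profile({("A", 1, "ALA"): 0.60, ("A", 2, "ALA"): 0.01, ("A", 3, "ALA"): 0.5})
        comp = _profile({("A", 1, "ALA"): 0.02, ("A", 2, "ALA"): 0.01, ("A", 3, "ALA"): 0.5})
        cls = classify_residues(mono, comp, exposed_threshold=0.2)
        assert cls.category == ["interface", "interior", "surface"]

    def test_partition_is_exhaustive_and_exclusive(self):
        rng = np.random.default_rng(0)
        residues = {("A", i, "ALA"): float(v) for i, v in enumerate(rng.uniform(0, 1, 50))}
        comp = {k: float(v) for k, v in zip(residues, rng.uniform(0, 1, 50))}
        cls = classify_residues(_profile(residues), _profile(comp))
        assert len(cls.residues) == 50
        assert set(cls.category) <= {"interface", "surface", "interior", "ligand-binding"}

    def test_ligand_binding_precedence_and_flag(self):
        mono = _profile({("A", 1, "ALA"): 0.6, ("A", 2, "ALA"): 0.6})
        comp = _profile({("A", 1, "ALA"): 0.02, ("A", 2, "ALA"): 0.6})
        cls = classify_residues(mono, comp, ligand_contacts={("A", 1, "ALA")})
        assert cls.category[0] == "ligand-binding"
        assert cls.ligand_binding[0] and not cls.ligand_binding[1]

    def test_mismatched_profiles_raise(self):
        mono = _profile({("A", 1, "ALA"): 0.6})
        comp = _profile({("A", 2, "ALA"): 0.6})
        with pytest.raises(StructureError, match="different residues"):
            classify_residues(mono, comp)


def _two_chain_structure(separation: float) -> Structure:
    atoms = [Atom("A", 1, "GLY", "CA", "C"), Atom("B", 1, "GLY", "CA", "C")]
    coords = np.array([[[0.0, 0.0, 0.0], [separation, 0.0, 0.0]]])
    return Structure(atoms, coords)


class TestContacts:
    def test_hand_placed_pair_at_3_5(self):
        s = _two_chain_structure(3.5)
        pairs = find_interface_pairs(s, "A", "B", cutoff=4.0)
        assert len(pairs) == 1
        assert pairs[0].distance == pytest.approx(3.5)

    def test_beyond_cutoff_is_empty(self):
        assert find_interface_pairs(_two_chain_structure(10.0), "A", "B") == []

    def test_symmetric_in_chain_order(self):
        s = _two_chain_structure(3.5)
        ab = find_interface_pairs(s, "A", "B")
        ba = find_interface_pairs(s, "B", "A")
        assert {(p.residue_a, p.residue_b) for p in ab} == {
            (p.residue_b, p.residue_a) for p in ba
        }

    def test_all_distances_below_cutoff(self):
        rng = np.random.default_rng(1)
        atoms, coords = [], []
        for c, base in (("A", 0.0), ("B", 3.0)):
            for i in range(8):
                atoms.append(Atom(c, i + 1, "GLY", "CA", "C"))
                coords.append(rng.uniform(0, 8, 3) + [base, 0, 0])
        s = Structure(atoms, np.array(coords)[None])
        pairs = find_interface_pairs(s, "A", "B", cutoff=4.0)
        assert all(p.distance < 4.0 for p in pairs)
        assert all(p.residue_a[0] == "A" and p.residue_b[0] == "B" for p in pairs)

    def test_missing_chain_raises(self):
        with pytest.raises(StructureError, match="chain"):
            find_interface_pairs(_two_chain_structure(3.5), "A", "Z")


class TestLigandContacts:
    def _with_ligand(self, dist: float) -> Structure:
        atoms = [
            Atom("A", 1, "GLY", "CA", "C"),
            Atom("A", 201, "MAN", "C1", "C", is_hetero=True),
        ]
        coords = np.array([[[0.0, 0.0, 0.0], [dist, 0.0, 0.0]]])
        return Structure(atoms, coords)

    def test_residue_within_cutoff_included(self):
        res = find_ligand_contacts(self._with_ligand(3.0), {"MAN"}, cutoff=3.9)
        assert res == {("A", 1, "GLY")}

    def test_isolated_ligand_gives_empty_set(self):
        assert find_ligand_contacts(self._with_ligand(12.0), {"MAN"}) == set()

    def test_no_matching_ligand_raises(self):
        with pytest.raises(StructureError, match="ligand"):
            find_ligand_contacts(self._with_ligand(3.0), {"NAG"})
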