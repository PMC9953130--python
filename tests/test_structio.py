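"""I/O, descriptors and rigid superposition."""

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pharmscreen as ps
from pharmscreen.structio import (Atom, FormatError, SchemaError,
                                  SelectorError, molecule_from_smiles)
from pharmscreen.pharmacophore import PharmacophoreFeature, PharmacophoreModel


# ---------------------------------------------------------------------------
# read_complex
# ---------------------------------------------------------------------------

class TestReadComplex:
    def test_extracts_selected_ligand_and_protein(self, tmp_path,
                                                  simple_pdb_text):
        p = tmp_path / "toy.pdb"
        p.write_text(simple_pdb_text)
        cx = ps.read_complex(p, "LIG")
        assert len(cx.ligand_atoms) == 5
        assert cx.ligand_id == "LIG"
        assert {a.residue_name for a in cx.protein_atoms} == \
            {"THR", "ALA", "ASP"}

    def test_waters_excluded_everywhere(self, tmp_path, simple_pdb_text):
        p = tmp_path / "toy.pdb"
        p.write_text(simple_pdb_text)
        cx = ps.read_complex(p, "LIG")
        names = {a.residue_name for a in cx.protein_atoms + cx.ligand_atoms}
        assert "HOH" not in names

    def test_ambiguous_ligand_needs_chain(self, tmp_path, simple_pdb_text):
        from tests.conftest import pdb_line

        extra = pdb_line(20, "C1", "LIG", "B", 900, (20, 20, 20), "C",
                         hetero=True)
        text = simple_pdb_text.replace("END", extra + "\nEND")
        p = tmp_path / "two.pdb"
        p.write_text(text)
        with pytest.raises(SelectorError, match="ambiguous"):
            ps.read_complex(p, "LIG")
        cx = ps.read_complex(p, "LIG", chain="A")
        assert len(cx.ligand_atoms) == 5

    def test_missing_ligand_names_candidates(self, tmp_path,
                                             simple_pdb_text):
        p = tmp_path / "toy.pdb"
        p.write_text(simple_pdb_text)
        with pytest.raises(SelectorError, match="LIG"):
            ps.read_complex(p, "XYZ")

    def test_unparseable_file_is_format_error(self, tmp_path):
        p = tmp_path / "junk.pdb"
        p.write_text("this is not a pdb file\n")
        with pytest.raises((FormatError, SelectorError)):
            ps.read_complex(p, "LIG")


# ---------------------------------------------------------------------------
# read_library / write_library
# ---------------------------------------------------------------------------

def _mol(name, n_conf=1, seed=0):
    rng = np.random.default_rng(seed)
    atoms = [Atom("C"), Atom("O", 0, 1), Atom("C")]
    bonds = [(0, 1, 1), (0, 2, 1)]
    confs = [rng.uniform(-5, 5, (3, 3)) for _ in range(n_conf)]
    return ps.SmallMolecule(name, atoms, bonds, confs, {"AlogP": "1.5"})


class TestLibraryIO:
    def test_distinct_names_stay_separate(self, tmp_path):
        p = tmp_path / "lib.sdf"
        ps.write_library(p, [_mol("a"), _mol("b")])
        lib = ps.read_library(p)
        assert [m.name for m in lib] == ["a", "b"]
        assert all(len(m.conformers) == 1 for m in lib)

    def test_same_name_records_merge_as_conformers(self, tmp_path):
        p = tmp_path / "lib.sdf"
        ps.write_library(p, [_mol("a", n_conf=3)])
        lib = ps.read_library(p)
        assert len(lib) == 1
        assert len(lib[0].conformers) == 3
        lib_unmerged = ps.read_library(p, merge_conformers=False)
        assert len(lib_unmerged) == 3

    def test_sdf_properties_round_trip(self, tmp_path):
        p = tmp_path / "lib.sdf"
        ps.write_library(p, [_mol("a")])
        lib = ps.read_library(p)
        assert lib[0].properties["AlogP"] == "1.5"

    def test_empty_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "empty.sdf"
        p.write_text("")
        assert ps.read_library(p) == []


# ---------------------------------------------------------------------------
# descriptors
# ---------------------------------------------------------------------------

class TestDescriptors:
    def test_methane_molecular_weight(self):
        mol = ps.SmallMolecule("methane", [Atom("C", 0, 4)], [],
                               [np.zeros((1, 3))])
        d = ps.compute_descriptors(mol)
        assert d.mw == pytest.approx(16.04, abs=0.01)

    def test_ethanol_donor_acceptor_counts(self):
        mol = molecule_from_smiles("CCO", "ethanol")
        d = ps.compute_descriptors(mol)
        assert (d.n_hbd, d.n_hba) == (1, 1)

    def test_aspirin_molecular_weight(self):
        # independent oracle: sum of standard atomic masses over C9H8O4
        expected = 9 * 12.011 + 8 * 1.008 + 4 * 15.999
        mol = molecule_from_smiles("CC(=O)Oc1ccccc1C(=O)O", "aspirin")
        d = ps.compute_descriptors(mol)
        assert d.mw == pytest.approx(expected, abs=0.02)
        assert d.mw == pytest.approx(180.16, abs=0.02)

    def test_conformer_independent(self):
        m1 = _mol("a", n_conf=1, seed=1)
        m2 = ps.SmallMolecule(m1.name, m1.atoms, m1.bonds,
                              [np.random.default_rng(9).uniform(-9, 9, (3, 3))],
                              m1.properties)
        assert ps.compute_descriptors(m1) == ps.compute_descriptors(m2)

    def test_unknown_element_raises(self):
        mol = ps.SmallMolecule("bad", [Atom("ZZ")], [], [np.zeros((1, 3))])
        with pytest.raises(ValueError, match="element"):
            ps.compute_descriptors(mol)


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def _rotation_about_z(deg):
    a = np.deg2rad(deg)
    return np.array([[np.cos(a), -np.sin(a), 0],
                     [np.sin(a), np.cos(a), 0],
                     [0, 0, 1.0]])


class TestSuperpose:
    def test_identity(self):
        P = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
        rt, rmsd = ps.superpose_points(P, P)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(rt.rotation, np.eye(3), atol=1e-9)

    def test_pure_translation_recovered(self):
        P = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
        Q = P - np.array([1.0, 2.0, 3.0])
        rt, rmsd = ps.superpose_points(P, Q)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(rt.translation, [1, 2, 3], atol=1e-9)

    def test_constructed_rotation_recovered(self):
        # oracle: build the rotation from axis-angle, verify round-trip
        R = _rotation_about_z(90.0)
        P = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 0.5]])
        Q = P @ R  # = R^T applied to each row
        rt, rmsd = ps.superpose_points(P, Q)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(rt.rotation, R, atol=1e-6)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            ps.superpose_points(np.zeros((0, 3)), np.zeros((0, 3)))

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_exact_recovery_property(self, seed):
        """superpose(P, R·P+t) has rmsd < 1e-9 for any proper rigid move."""
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 12))
        P = rng.uniform(-10, 10, (n, 3))
        R = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
        t = rng.uniform(-10, 10, 3)
        Q = P @ R.T + t
        # transform mapping Q back onto P
        rt, rmsd = ps.superpose_points(P, Q)
        assert rmsd < 1e-9

    def test_inverse_round_trip(self):
        rt = ps.RigidTransform(_rotation_about_z(37.0), np.array([1, 2, 3.0]))
        pts = np.random.default_rng(0).uniform(-5, 5, (7, 3))
        assert np.allclose(rt.inverse().apply(rt.apply(pts)), pts, atol=1e-9)


# ---------------------------------------------------------------------------
# model JSON
# ---------------------------------------------------------------------------

class TestModelJSON:
    def _model(self):
        feats = [
            PharmacophoreFeature("HBA", (1, 2, 3), 1.6, (4, 5, 6), 2.2,
                                 "A208", "toy-A"),
            PharmacophoreFeature("HYP", (0, 0, 0), 1.6, None, 2.2,
                                 "L132|L259", "toy-A|toy-B"),
        ]
        return PharmacophoreModel("m", feats, ["toy-A", "toy-B"], "toy-A")

    def test_round_trip_is_lossless(self, tmp_path):
        p = tmp_path / "m.json"
        model = self._model()
        ps.write_model(p, model)
        assert ps.read_model(p) == model

    def test_missing_tolerance_is_schema_error(self, tmp_path):
        p = tmp_path / "m.json"
        doc = self._model().to_dict()
        del doc["features"][0]["tolerance"]
        p.write_text(json.dumps(doc))
        with pytest.raises(SchemaError, match="tolerance"):
            ps.read_model(p)

    def test_empty_feature_list_is_valid(self, tmp_path):
        p = tmp_path / "m.json"
        model = PharmacophoreModel("empty", [], [], None)
        ps.write_model(p, model)
        assert ps.read_model(p).features == []
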