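"""Rule-of-five filtering, feature perception, fit scoring and mapping."""

import numpy as np
import pytest

import pharmscreen as ps
from pharmscreen.screening import perceive_features
from pharmscreen.structio import Atom, DescriptorSet, molecule_from_smiles

from tests.conftest import brute_force_map, random_rigid_transform


class TestRofFilter:
    @pytest.mark.parametrize("d,expected", [
        (DescriptorSet(500.0, 5, 10, 5.0), True),   # inclusive boundary
        (DescriptorSet(501.0, 0, 0, 0.0), False),
        (DescriptorSet(180.0, 6, 0, 0.0), False),
        (DescriptorSet(180.0, 0, 11, 0.0), False),
        (DescriptorSet(180.0, 0, 0, 5.01), False),
        (DescriptorSet(180.2, 1, 4, 1.3), True),
    ])
    def test_thresholds(self, d, expected):
        assert ps.rof_filter(d) is expected

    def test_planted_violation_fraction_recounted(self):
        rng = np.random.default_rng(17)
        descriptors = []
        for _ in range(200):
            violate = rng.random() < 0.3
            mw = float(rng.uniform(501, 900)) if violate \
                else float(rng.uniform(100, 500))
            descriptors.append(DescriptorSet(mw, 1, 2, 1.0))
        # oracle: direct rule application
        expected = sum(1 for d in descriptors if d.mw <= 500)
        assert sum(ps.rof_filter(d) for d in descriptors) == expected


class TestPerceiveFeatures:
    def test_ethanol_oxygen_is_donor_and_acceptor(self):
        pts = perceive_features(molecule_from_smiles("CCO"))
        kinds = [p.kind for p in pts]
        assert kinds.count("HBD") == 1
        assert kinds.count("HBA") == 1
        assert kinds.count("HYP") == 0

    def test_benzene_single_hydrophobe(self):
        pts = perceive_features(molecule_from_smiles("c1ccccc1"))
        assert [p.kind for p in pts] == ["HYP"]
        assert len(pts[0].atom_indices) == 6

    def test_hexane_chain_hydrophobe_at_centroid(self):
        mol = molecule_from_smiles("CCCCCC")
        pts = perceive_features(mol)
        assert [p.kind for p in pts] == ["HYP"]
        np.testing.assert_allclose(
            pts[0].centroid, mol.conformers[0].mean(axis=0), atol=1e-9)

    def test_amide_nitrogen_not_acceptor(self):
        pts = perceive_features(molecule_from_smiles("CC(=O)NC"))
        hba_atoms = [p.atom_indices[0] for p in pts if p.kind == "HBA"]
        mol = molecule_from_smiles("CC(=O)NC")
        assert all(mol.atoms[i].element == "O" for i in hba_atoms)

    def test_planted_inventory_recovered(self, hybrid_model):
        lib, _labels, truth = ps.make_labeled_library(
            hybrid_model, ps.LibrarySpec(n_active=3, n_decoy=0, seed=5))
        want_kinds = sorted(f.kind for f in hybrid_model.features)
        for mol in lib:
            got = [p.kind for p in perceive_features(mol, 0)]
            # every model feature kind is realized at least as often as needed
            for kind in set(want_kinds):
                assert got.count(kind) >= want_kinds.count(kind)


class TestFitScore:
    def test_perfect_hits_score_feature_count(self):
        assert ps.fit_score([0, 0, 0], [1.6, 1.6, 1.6]) == pytest.approx(3.0)

    def test_boundary_scores_zero(self):
        assert ps.fit_score([1.6], [1.6]) == pytest.approx(0.0)

    def test_half_displacement(self):
        # oracle by hand: 1 - (0.8/1.6)^2 = 0.75
        assert ps.fit_score([0.8], [1.6]) == pytest.approx(0.75)

    def test_out_of_tolerance_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            ps.fit_score([2.0], [1.6])

    def test_weights(self):
        assert ps.fit_score([0, 0.8], [1.6, 1.6], [2.0, 4.0]) == \
            pytest.approx(2.0 + 3.0)


class TestMapConformer:
    def test_exact_points_map_with_full_fit(self, hybrid_model):
        lib, _labels, truth = ps.make_labeled_library(
            hybrid_model,
            ps.LibrarySpec(n_active=1, n_decoy=0, margin_in=0.01, seed=8))
        res = ps.map_conformer(lib[0], 0, hybrid_model)
        assert res is not None
        assert res.n_omitted == 0
        assert res.fit == pytest.approx(len(hybrid_model.features), abs=0.05)

    def test_missing_required_kind_fails(self, hybrid_model):
        mol = ps.SmallMolecule(
            "noface", [Atom("C"), Atom("C"), Atom("C"), Atom("C")],
            [(0, 1, 1), (1, 2, 1), (2, 3, 1)],
            [np.random.default_rng(0).uniform(-3, 3, (4, 3))])
        assert ps.map_conformer(mol, 0, hybrid_model) is None

    def test_rigid_invariance_of_fit(self, hybrid_model):
        lib, _l, _t = ps.make_labeled_library(
            hybrid_model, ps.LibrarySpec(n_active=1, n_decoy=0, seed=9))
        mol = lib[0]
        base = ps.map_conformer(mol, 0, hybrid_model)
        rng = np.random.default_rng(2)
        rt = random_rigid_transform(rng)
        moved = ps.SmallMolecule(mol.name, mol.atoms, mol.bonds,
                                 [rt.apply(mol.conformers[0])],
                                 mol.properties)
        res = ps.map_conformer(moved, 0, hybrid_model)
        assert res is not None
        assert res.fit == pytest.approx(base.fit, abs=1e-6)

    def test_tolerance_growth_is_monotone(self, hybrid_model):
        from dataclasses import replace

        lib, _l, _t = ps.make_labeled_library(
            hybrid_model, ps.LibrarySpec(n_active=3, n_decoy=3, seed=10))
        grown = ps.PharmacophoreModel(
            "wide", [replace(f, tolerance=f.tolerance * 1.5)
                     for f in hybrid_model.features],
            hybrid_model.provenance, hybrid_model.frame)
        for mol in lib:
            if ps.map_conformer(mol, 0, hybrid_model) is not None:
                assert ps.map_conformer(mol, 0, grown) is not None

    def test_matches_brute_force_on_perturbed_cases(self, hybrid_model):
        """Pruned search agrees with exhaustive correspondence enumeration."""
        lib, _l, _t = ps.make_labeled_library(
            hybrid_model, ps.LibrarySpec(n_active=6, n_decoy=6, seed=11))
        rng = np.random.default_rng(12)
        checked = 0
        for mol in lib:
            noisy = ps.perturb_conformer(mol, float(rng.uniform(0, 1.2)),
                                         int(rng.integers(2**31)))
            got = ps.map_conformer(noisy, 0, hybrid_model)
            want = brute_force_map(noisy, 0, hybrid_model)
            assert (got is None) == (want is None)
            if got is not None:
                assert got.fit == pytest.approx(want[0], abs=1e-9)
            checked += 1
        assert checked == 12

    def test_omission_allows_partial_match(self, hybrid_model):
        lib, _l, truth = ps.make_labeled_library(
            hybrid_model, ps.LibrarySpec(n_active=0, n_decoy=4, seed=13))
        params = ps.MappingParams(max_omit=1)
        for mol, t in zip(lib, truth):
            strict = ps.map_conformer(mol, 0, hybrid_model)
            relaxed = ps.map_conformer(mol, 0, hybrid_model, params)
            assert strict is None
            # omitting the violated feature rescues the decoy
            assert relaxed is not None and relaxed.n_omitted <= 1
            want = brute_force_map(mol, 0, hybrid_model, max_omit=1)
            assert relaxed.fit == pytest.approx(want[0], abs=1e-9)


class TestScreenLibrary:
    def test_planted_actives_counted(self, hybrid_model):
        lib, _l, _t = ps.make_labeled_library(
            hybrid_model, ps.LibrarySpec(n_active=4, n_decoy=6, seed=14))
        hits, funnel = ps.screen_library(lib, hybrid_model)
        assert funnel.n_mapped == 4
        assert {m.name for m, _ in hits} == \
            {f"active_{i:03d}" for i in range(4)}

    def test_empty_library(self, hybrid_model):
        hits, funnel = ps.screen_library([], hybrid_model)
        assert hits == []
        assert funnel == ps.FunnelStats(0, 0, 0, 0)

    def test_rof_violators_not_mapped(self, hybrid_model):
        lib, _l, _t = ps.make_labeled_library(
            hybrid_model, ps.LibrarySpec(n_active=3, n_decoy=0, seed=15))
        for mol in lib:
            mol.properties["AlogP"] = "9.0"  # force a rule-of-five violation
        hits, funnel = ps.screen_library(lib, hybrid_model)
        assert funnel.n_druglike == 0 and funnel.n_mapped == 0

    def test_funnel_monotone_and_hits_sorted(self, hybrid_model):
        lib, _l, _t = ps.make_labeled_library(
            hybrid_model, ps.LibrarySpec(n_active=5, n_decoy=10, seed=16))
        hits, funnel = ps.screen_library(lib, hybrid_model)
        assert funnel.n_input >= funnel.n_druglike >= funnel.n_mapped \
            >= funnel.n_selected
        fits = [r.fit for _, r in hits]
        assert fits == sorted(fits, reverse=True)
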