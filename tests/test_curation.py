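"""Curation protocol: per-step rules, ordering, conservation, idempotence."""

import pytest
from rdkit import Chem

import abcc2pred as a
from abcc2pred import curation


def rec(smiles, rid="X", pcc=None):
    return a.MoleculeRecord(id=rid, mol=Chem.MolFromSmiles(smiles), pcc=pcc)


class TestIndividualSteps:
    @pytest.mark.parametrize(
        "smiles,kept",
        [("O", False), ("[Na+].[Cl-]", False), ("c1ccccc1", True), ("[C-]#N.CC[NH3+]", True)],
    )
    def test_inorganic_rule_requires_carbon(self, smiles, kept):
        out, report = curation.remove_inorganics([rec(smiles)])
        assert bool(out) is kept
        assert report.n_input == 1 and report.n_removed == (0 if kept else 1)

    def test_salt_stripped_to_organic_parent(self):
        out, reason = curation.resolve_mixture(rec("CC(=O)Oc1ccccc1C(=O)O.Cl"))
        assert reason is None
        assert Chem.MolToSmiles(out.mol) == Chem.MolToSmiles(
            Chem.MolFromSmiles("CC(=O)Oc1ccccc1C(=O)O")
        )

    def test_two_organics_removed(self):
        out, reason = curation.resolve_mixture(rec("c1ccccc1.Cc1ccccc1"))
        assert out is None and "organic" in reason

    def test_single_component_unchanged(self):
        r = rec("CCO")
        before = r.smiles
        out, reason = curation.resolve_mixture(r)
        assert out is r and out.smiles == before

    @pytest.mark.parametrize(
        "smiles,kept",
        [("C[Hg]Cl", False), ("Clc1ccccc1", True), ("CC[Pb](CC)(CC)CC", False)],
    )
    def test_metal_rule(self, smiles, kept):
        out, _ = curation.remove_organometallics([rec(smiles)])
        assert bool(out) is kept

    @pytest.mark.parametrize(
        "smiles,kept",
        [
            ("C[Se]CCC(N)C(=O)O", False),       # selenium
            ("c1ccc([Te]C)cc1", False),         # tellurium
            ("Brc1ccc(Cl)c(I)c1", True),        # halogens stay computable
        ],
    )
    def test_special_atom_rule(self, smiles, kept):
        out, _ = curation.remove_special_atoms([rec(smiles)])
        assert bool(out) is kept

    def test_standardize_clears_stereo(self):
        out, _ = curation.standardize(rec("C[C@H](N)C(=O)O"))
        flat, _ = curation.standardize(rec("CC(N)C(=O)O"))
        assert out.smiles == flat.smiles
        assert "@" not in out.smiles

    def test_standardize_neutralizes_carboxylate(self):
        out, _ = curation.standardize(rec("CC(=O)[O-]"))
        assert Chem.GetFormalCharge(out.mol) == 0
        assert out.smiles == "CC(=O)O"

    def test_standardize_unifies_nitro_depictions(self):
        charge_sep, _ = curation.standardize(rec("[O-][N+](=O)c1ccccc1"))
        neutral, _ = curation.standardize(rec("O=N(=O)c1ccccc1"))
        assert charge_sep.smiles == neutral.smiles

    def test_standardize_is_idempotent(self):
        once, _ = curation.standardize(rec("[O-]C(=O)c1ccc(C(C)N)cc1"))
        twice, _ = curation.standardize(once)
        assert once.smiles == twice.smiles

    def test_conflicting_pcc_duplicates_all_deleted(self):
        pair = [rec("OC1CCCCC1", "d1", -0.40), rec("OC1CCCCC1", "d2", -0.10)]
        out, report = curation.deduplicate(pair)
        assert out == []
        assert {i for i, _ in report.removed} == {"d1", "d2"}

    def test_agreeing_duplicates_keep_first(self):
        pair = [rec("OC1CCCCC1", "d1", -0.40), rec("OC1CCCCC1", "d2", -0.40)]
        out, report = curation.deduplicate(pair)
        assert [r.id for r in out] == ["d1"]
        assert report.n_removed == 1

    def test_distinct_structures_untouched(self):
        records = [rec("CCO", "a", 0.1), rec("CCC", "b", 0.1)]
        out, report = curation.deduplicate(records)
        assert len(out) == 2 and report.n_removed == 0

    @pytest.mark.parametrize(
        "smiles,kept",
        [
            ("C[N+](C)(C)C", False),                  # quaternary ammonium
            ("CC(=O)O", True),
            ("[NH3+]CC(=O)[O-]", True),               # net-zero zwitterion
        ],
    )
    def test_permanent_charge_rule_tests_net_charge(self, smiles, kept):
        out, _ = curation.remove_permanent_charges([rec(smiles)])
        assert bool(out) is kept


class TestChargeAssignment:
    @pytest.mark.parametrize(
        "smiles,charge",
        [
            ("OC(=O)c1ccccc1", -1),   # benzoic acid -> benzoate
            ("CCCN", +1),             # n-propylamine -> propylammonium
            ("CC(=O)Nc1ccccc1", 0),   # acetanilide: no strong acid/base
            ("NC(=N)c1ccccc1", +1),   # benzamidine
            ("OS(=O)(=O)c1ccccc1", -1),
        ],
    )
    def test_strong_acid_base_rules(self, smiles, charge):
        out = curation.assign_charge_states([rec(smiles)])
        assert Chem.GetFormalCharge(out[0].mol) == charge

    def test_amide_and_aromatic_nitrogens_not_protonated(self):
        out = curation.assign_charge_states([rec("O=C(NC)c1ccncc1")])
        assert Chem.GetFormalCharge(out[0].mol) == 0


class TestRunCuration:
    def test_dirty_fixture_counts_derived_by_hand(self):
        # 9 clean + 11 annotated dirty records = 20 in; applying the seven
        # rules by hand: 2 inorganic + 2 mixtures + 2 organometallic + 1 Se
        # + 1 permanent cation + 2 conflicting duplicates removed (10), the
        # salt survives desalted -> 10 out
        lib = a.generate_library(a.SimulationConfig(n_compounds=9, seed=3))
        assert len(lib.records) == 20
        ds, report = a.run_curation(lib.records)
        assert report.initial_count == 20
        assert report.final_count == 10
        removed = {i for s in report.steps for i, _ in s.removed}
        expected_removed = {
            i for i, fate in lib.truth["dirty"].items() if fate.startswith("remove:")
        }
        assert removed == expected_removed

    def test_empty_input(self):
        ds, report = a.run_curation([])
        assert len(ds) == 0 and report.final_count == 0

    def test_count_conservation_invariant(self, curated):
        _, report = curated
        report.validate()
        for prev, nxt in zip(report.steps, report.steps[1:]):
            assert nxt.n_input == prev.n_output

    def test_idempotence_second_pass_removes_nothing(self, curated):
        ds, _ = curated
        ds2, report2 = a.run_curation(list(ds.records))
        assert report2.total_removed == 0
        assert [r.smiles for r in ds2.records] == [r.smiles for r in ds.records]

    def test_metal_counterion_salt_survives_because_mixtures_resolve_first(self):
        # sodium benzoate: step 2 strips Na+ before the metal check fires
        ds, report = a.run_curation([rec("[O-]C(=O)c1ccccc1.[Na+]", "nabz", -0.1)])
        assert len(ds) == 1
        assert ds.records[0].smiles == "O=C(O)c1ccccc1"

    def test_neutral_variant_leaves_no_net_charge(self, curated):
        ds, _ = curated
        assert all(Chem.GetFormalCharge(r.mol) == 0 for r in ds.records)

    def test_charged_variant_ionizes_strong_groups(self):
        records = [rec("OC(=O)CCCCN", "aa", -0.2), rec("CCOCC", "e", 0.0)]
        ds, _ = a.run_curation(records, a.CurationConfig(charge_variant="charged"))
        by_id = {r.id: r for r in ds.records}
        assert Chem.GetFormalCharge(by_id["aa"].mol) == 0  # acid -1, amine +1
        smiles = by_id["aa"].smiles
        assert "[O-]" in smiles or "O-]" in smiles
        assert Chem.GetFormalCharge(by_id["e"].mol) == 0
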