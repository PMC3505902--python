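"""Descriptor panel: printed-value checks, conservation laws, fingerprints."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from rdkit import Chem

import abcc2pred as a
from abcc2pred import descriptors as D


def desc(smiles, panel="table3"):
    return a.compute_descriptors(Chem.MolFromSmiles(smiles), panel=panel)


class TestPanelValues:
    def test_benzene(self):
        d = desc("c1ccccc1")
        assert d["TPSA"] == 0.0
        assert d["rings"] == 1
        assert d["a_don"] == 0
        assert d["a_nCl"] == 0

    def test_tetrachloromethane(self):
        d = desc("ClC(Cl)(Cl)Cl")
        assert d["a_nCl"] == 4
        assert d["rings"] == 0
        assert d["b_count"] == 4

    def test_phenol_donor_and_tpsa(self):
        # single hydroxyl: one donor; TPSA equals the published O-H
        # fragment contribution 20.23 A^2
        d = desc("Oc1ccccc1")
        assert d["a_don"] == 1
        assert d["TPSA"] == pytest.approx(20.23, abs=1e-9)

    def test_counts_are_non_negative_integers(self, curated):
        ds, _ = curated
        count_names = ["a_don", "a_nBr", "a_nCl", "a_nN", "a_nO", "a_nS",
                       "b_count", "rings", "vsa_base"]
        for r in ds.records[:25]:
            d = a.compute_descriptors(r)
            for name in count_names:
                assert d[name] >= 0 and d[name] == int(d[name])

    def test_determinism_bitwise(self, curated):
        ds, _ = curated
        r = ds.records[0]
        assert a.compute_descriptors(r) == a.compute_descriptors(r)

    def test_chlorine_substitution_increments_a_nCl_by_one(self):
        pairs = [
            ("c1ccccc1", "Clc1ccccc1"),
            ("CCO", "CC(Cl)O"),
            ("Clc1ccccc1", "Clc1ccccc1Cl"),
            ("c1ccc2ccccc2c1", "Clc1ccc2ccccc2c1"),
        ]
        for base, chloro in pairs:
            assert desc(chloro)["a_nCl"] == desc(base)["a_nCl"] + 1


class TestChargeBinConservation:
    def test_fneg_fpos_fractions(self, curated):
        ds, _ = curated
        for r in ds.records[:30]:
            d = a.compute_descriptors(r)
            assert 0.0 <= d["PEOE_VSA_FNEG"] <= 1.0
            assert 0.0 <= d["PEOE_VSA_FPOS"] <= 1.0
            assert d["PEOE_VSA_FNEG"] + d["PEOE_VSA_FPOS"] <= 1.0 + 1e-9

    def test_all_charge_bins_sum_to_total_vsa(self, curated):
        ds, _ = curated
        for r in ds.records[:30]:
            d = a.compute_descriptors(r, panel="extended")
            bins = [n for n in d if n.startswith("PEOE_VSA+") or n.startswith("PEOE_VSA-")]
            assert sum(d[n] for n in bins) == pytest.approx(d["VSA_total"], abs=1e-6)

    def test_pos_equals_fraction_times_total(self, curated):
        ds, _ = curated
        for r in ds.records[:30]:
            d = a.compute_descriptors(r, panel="extended")
            assert d["PEOE_VSA_POS"] == pytest.approx(
                d["PEOE_VSA_FPOS"] * d["VSA_total"], abs=1e-6
            )
            assert d["PEOE_VSA_NEG"] == pytest.approx(
                d["PEOE_VSA_FNEG"] * d["VSA_total"], abs=1e-6
            )


class TestZscore:
    def test_closed_form_three_values(self):
        # population sd of [1,2,3] is sqrt(2/3); (3-2)/sd = 1.22474
        m = D.DescriptorMatrix(values=pd.DataFrame({"x": [1.0, 2.0, 3.0]}))
        zm, params = a.zscore(m)
        np.testing.assert_allclose(
            zm.values["x"].to_numpy(), [-1.224745, 0.0, 1.224745], atol=1e-6
        )

    def test_constant_column_zeroed_and_flagged(self):
        m = D.DescriptorMatrix(values=pd.DataFrame({"x": [5.0, 5.0, 5.0],
                                                    "y": [1.0, 2.0, 4.0]}))
        zm, params = a.zscore(m)
        assert params.constant == ["x"]
        assert (zm.values["x"] == 0.0).all()

    def test_column_moments_after_scoring(self, zmatrix):
        zm, params = zmatrix
        live = [c for c in zm.names if c not in params.constant]
        means = zm.values[live].mean(axis=0)
        sds = zm.values[live].std(axis=0, ddof=0)
        assert np.allclose(means, 0.0, atol=1e-9)
        assert np.allclose(sds, 1.0, atol=1e-9)

    def test_training_params_applied_to_new_data(self):
        m = D.DescriptorMatrix(values=pd.DataFrame({"x": [1.0, 2.0, 3.0]}))
        _, params = a.zscore(m)
        new = D.DescriptorMatrix(values=pd.DataFrame({"x": [2.0]}))
        znew, _ = a.zscore(new, params)
        assert znew.values["x"].iloc[0] == pytest.approx(0.0)

    def test_roundtrip_params_dict(self):
        m = D.DescriptorMatrix(values=pd.DataFrame({"x": [1.0, 2.0, 4.0]}))
        _, params = a.zscore(m)
        restored = D.NormalizationParams.from_dict(params.to_dict())
        new = D.DescriptorMatrix(values=pd.DataFrame({"x": [4.0]}))
        z1, _ = a.zscore(new, params)
        z2, _ = a.zscore(new, restored)
        assert z1.values.equals(z2.values)


class TestStructuralKeys:
    def test_methane_nearly_empty(self):
        fp = a.maccs_keys(Chem.MolFromSmiles("C"))
        assert len(fp) <= 2

    def test_identical_structures_identical_keys(self, curated):
        ds, _ = curated
        r = ds.records[0]
        assert a.maccs_keys(r).bits == a.maccs_keys(Chem.MolFromSmiles(r.smiles)).bits

    def test_benzene_vs_cyclohexane_differ_in_aromatic_bits(self):
        fb = a.maccs_keys(Chem.MolFromSmiles("c1ccccc1"))
        fc = a.maccs_keys(Chem.MolFromSmiles("C1CCCCC1"))
        assert fb.bits != fc.bits
        # key 162 is the aromaticity key in the public 166-key set
        assert 162 in fb.bits and 162 not in fc.bits


def _fp(bits):
    return a.StructuralKeyFingerprint(bits=frozenset(bits))


class TestTanimoto:
    def test_identical_nonempty_is_one(self):
        assert a.tanimoto(_fp({1, 5, 9}), _fp({1, 5, 9})) == 1.0

    def test_disjoint_is_zero(self):
        assert a.tanimoto(_fp({1, 2}), _fp({3, 4})) == 0.0

    def test_worked_example(self):
        # |A|=4, |B|=3, |A∩B|=2 -> 2/(4+3-2) = 0.4
        assert a.tanimoto(_fp({1, 2, 3, 4}), _fp({3, 4, 5})) == pytest.approx(0.4)

    def test_both_empty_is_one(self):
        assert a.tanimoto(_fp(set()), _fp(set())) == 1.0

    def test_length_mismatch_raises(self):
        other = a.StructuralKeyFingerprint(bits=frozenset({1}), n_keys=10)
        with pytest.raises(ValueError, match="mismatch"):
            a.tanimoto(_fp({1}), other)

    @settings(max_examples=50, deadline=None)
    @given(
        st.frozensets(st.integers(1, 166), max_size=40),
        st.frozensets(st.integers(1, 166), max_size=40),
    )
    def test_symmetry_and_bounds(self, bits_a, bits_b):
        s = a.tanimoto(_fp(bits_a), _fp(bits_b))
        assert s == a.tanimoto(_fp(bits_b), _fp(bits_a))
        assert 0.0 <= s <= 1.0
        if bits_a:
            assert a.tanimoto(_fp(bits_a), _fp(bits_a)) == 1.0
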