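"""Generation metrics against set-arithmetic oracles and fixed fixtures."""

import numpy as np
import pytest
from rdkit import Chem

from ligandgen.evaluation import (ReferenceSet, canonicalize, evaluate_run,
                                  novelty, property_table, tanimoto_pair,
                                  tanimoto_profile, unique_at_k, validity)

VALID_POOL = ["CCO", "CCN", "CCC", "c1ccccc1", "Cc1ccccc1", "CCOC", "CC(C)O",
              "c1ccncc1", "CC(N)=O", "CCCl"]


class TestValidity:
    def test_half_valid(self):
        frac, valid = validity(["CCO", "C(("])
        assert frac == 0.5 and valid == ["CCO"]

    def test_all_valid(self):
        frac, _ = validity(VALID_POOL)
        assert frac == 1.0

    def test_empty_list_nan_with_warning(self):
        with pytest.warns(UserWarning):
            frac, valid = validity([])
        assert np.isnan(frac) and valid == []


class TestUnique:
    def test_first_k_with_duplicate(self):
        assert unique_at_k(["CCO", "CCO", "CCN"], 3) == pytest.approx(2 / 3)

    def test_all_distinct(self):
        assert unique_at_k(VALID_POOL, len(VALID_POOL)) == 1.0

    def test_canonical_identity(self):
        # "OCC" is ethanol written backwards: one structure, not two
        assert unique_at_k(["CCO", "OCC"], 2) == 0.5

    def test_shortfall_warns_and_uses_all(self):
        with pytest.warns(UserWarning):
            got = unique_at_k(["CCO", "CCN"], 5)
        assert got == 1.0

    def test_duplicates_never_raise_the_metric(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            k = int(rng.integers(2, 8))
            base = list(rng.choice(VALID_POOL, size=k, replace=True))
            with_dup = [base[0]] + base[:k - 1]
            assert (unique_at_k(with_dup, k)
                    <= unique_at_k(base, k) + 1e-12)


class TestNovelty:
    def test_forced_fraction(self):
        ref = ReferenceSet.from_smiles(["CCN"])
        assert novelty(["CCO", "CCN", "CCC"], ref) == pytest.approx(2 / 3)

    def test_subset_of_reference_is_zero(self):
        ref = ReferenceSet.from_smiles(VALID_POOL)
        assert novelty(VALID_POOL[:4], ref) == 0.0

    def test_disjoint_sets_is_one(self):
        ref = ReferenceSet.from_smiles(["c1ccsc1"])
        assert novelty(["CCO", "CCN"], ref) == 1.0

    def test_self_reference_identity(self):
        ref = ReferenceSet.from_smiles(VALID_POOL)
        assert novelty(VALID_POOL, ref) == 0.0

    def test_empty_reference_warns_one(self):
        with pytest.warns(UserWarning):
            assert novelty(["CCO"], ReferenceSet.from_smiles([])) == 1.0

    def test_set_arithmetic_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            gen = list(rng.choice(VALID_POOL, size=int(rng.integers(1, 10)),
                                  replace=True))
            ref_list = list(rng.choice(VALID_POOL,
                                       size=int(rng.integers(1, 6)),
                                       replace=False))
            ref = ReferenceSet.from_smiles(ref_list)
            want_set = {canonicalize(s) for s in gen}
            want = len(want_set - set(ref.canonical)) / len(want_set)
            assert novelty(gen, ref) == pytest.approx(want)


class TestProperties:
    def test_ethanol_molecular_weight(self):
        # 2 C (12.011) + 6 H (1.008) + O (15.999) = 46.069 Da
        row = property_table(["CCO"]).iloc[0]
        assert row["MW"] == pytest.approx(2 * 12.011 + 6 * 1.008 + 15.999,
                                          abs=0.01)

    def test_ranges(self):
        df = property_table(VALID_POOL)
        assert ((df["QED"] >= 0) & (df["QED"] <= 1)).all()
        assert ((df["SAscore"] >= 1) & (df["SAscore"] <= 10)).all()
        assert not df["flagged"].any()

    def test_sa_matches_published_fragment_scorer(self):
        import sascorer
        for s in VALID_POOL[:5]:
            got = property_table([s])["SAscore"].iloc[0]
            want = sascorer.calculateScore(Chem.MolFromSmiles(s))
            assert got == pytest.approx(want, abs=1e-9)


class TestTanimoto:
    def test_identity_and_range(self):
        ref = ReferenceSet.from_smiles(VALID_POOL)
        sims, mx = tanimoto_profile("CCO", ref)
        assert mx == 1.0
        assert ((sims >= 0) & (sims <= 1)).all()

    def test_pair_values(self):
        assert tanimoto_pair("CCO", "CCO") == 1.0
        assert tanimoto_pair("C", "c1ccccc1") < 0.5

    def test_bitset_oracle(self):
        from rdkit.Chem import rdFingerprintGenerator
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)
        a = set(gen.GetFingerprint(Chem.MolFromSmiles("CCO")).GetOnBits())
        b = set(gen.GetFingerprint(Chem.MolFromSmiles("CCN")).GetOnBits())
        want = len(a & b) / len(a | b)
        assert tanimoto_pair("CCO", "CCN") == pytest.approx(want)


class TestEvaluateRun:
    def test_constructed_fixture_exact_values(self):
        """10 generated: 8 valid, one duplicate pair, one reference hit."""
        generated = ["CCO", "CCN", "CCC", "CCO", "c1ccccc1", "Cc1ccccc1",
                     "CCOC", "CC(C)O", "C((", "xyz"]
        ref = ReferenceSet.from_smiles(["CCN"])
        report = evaluate_run(generated, ref, ks=(8,), sample_size=100,
                              seed=0, with_tanimoto=False)
        assert report.valid == pytest.approx(0.8)
        assert report.unique_at_k[8] == pytest.approx(7 / 8)
        assert report.novelty == pytest.approx(6 / 7)

    def test_oversized_sample_warns(self):
        ref = ReferenceSet.from_smiles([])
        with pytest.warns(UserWarning):
            evaluate_run(["CCO"], ref, ks=(1,), sample_size=10, seed=0)

    def test_seeded_subsample_reproducible(self):
        rng = np.random.default_rng(3)
        gen = list(rng.choice(VALID_POOL, size=50, replace=True))
        ref = ReferenceSet.from_smiles(VALID_POOL[:3])
        a = evaluate_run(gen, ref, ks=(5,), sample_size=20, seed=9)
        b = evaluate_run(gen, ref, ks=(5,), sample_size=20, seed=9)
        assert a.to_dict() == b.to_dict()
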