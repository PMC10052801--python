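"""Curation rules: binarization, sanitization, tokenization, ledger."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from rdkit import Chem

from ligandgen.curation import (CurationLedger, binarize_activity, curate,
                                filter_protein, pairs_to_frame,
                                sanitize_smiles, tokenize_smiles)
from ligandgen.vocab import (SmilesVocabulary, ProteinVocabulary,
                             SMILES_TOKENS, AMINO_ACIDS, dp_tokenize)


class TestBinarize:
    @pytest.mark.parametrize("activities,expected", [
        ([1, 2, 3], [0, 0, 1]),        # median 2; only 3 exceeds it
        ([5, 5, 5], [0, 0, 0]),        # nothing strictly exceeds the median
        ([1, 4], [0, 1]),              # even n: median 2.5
    ])
    def test_single_target(self, activities, expected):
        recs = [("T", a) for a in activities]
        assert [l for _, l in binarize_activity(recs)] == expected

    def test_per_target_independence(self):
        recs = [("A", 1), ("A", 4), ("B", 10), ("B", 2)]
        assert [l for _, l in binarize_activity(recs)] == [0, 1, 1, 0]

    def test_empty_input(self):
        assert binarize_activity([]) == []

    def test_tie_convention_flip(self):
        recs = [("T", 2.0), ("T", 2.0)]
        assert [l for _, l in binarize_activity(recs)] == [0, 0]
        assert [l for _, l in binarize_activity(recs, ties_to_zero=False)] == [1, 1]


class TestSanitize:
    def test_stereo_removed_and_canonicalized(self):
        # oracle: canonicalize the explicitly destereoized structure
        expected = Chem.MolToSmiles(Chem.MolFromSmiles("CC(N)C(=O)O"))
        assert sanitize_smiles("C[C@H](N)C(=O)O") == expected

    def test_salt_dropped_largest_fragment_kept(self):
        expected = Chem.MolToSmiles(Chem.MolFromSmiles("CCO"))
        assert sanitize_smiles("CCO.[Na+]") == expected

    @pytest.mark.parametrize("bad,rule", [
        ("[Si](C)(C)C", "uncommon_atom"),
        ("O=S(=O)(O)O", "inorganic"),      # no carbon
        ("C((", "invalid_smiles"),
        ("", "invalid_smiles"),
    ])
    def test_rejections_hit_the_right_ledger_rule(self, bad, rule):
        ledger = CurationLedger(n_in=1)
        assert sanitize_smiles(bad, ledger) is None
        assert ledger.dropped[rule] == 1


class TestTokenizer:
    @pytest.mark.parametrize("smiles,tokens", [
        ("CCl", ["C", "Cl"]),
        ("c1cc[nH]c1", ["c", "1", "c", "c", "[nH]", "c", "1"]),
        ("BrC=O", ["Br", "C", "=", "O"]),
    ])
    def test_longest_match(self, smiles, tokens):
        assert tokenize_smiles(smiles) == tokens

    def test_unknown_symbol_rejects(self):
        assert tokenize_smiles("CC%10") is None

    def test_round_trip(self, fixture_smiles_500):
        vocab = SmilesVocabulary()
        for s in fixture_smiles_500:
            assert "".join(vocab.tokenize(s)) == s

    def test_greedy_agrees_with_dp_oracle(self, fixture_smiles_500):
        """For this vocabulary greedy longest-match is the unique
        segmentation; a brute-force DP tokenizer must agree on 1000 strings."""
        vocab = SmilesVocabulary()
        rng = np.random.default_rng(0)
        pool = fixture_smiles_500
        picks = rng.choice(len(pool), size=1000, replace=True)
        for i in picks:
            s = pool[i]
            assert dp_tokenize(s) == [vocab.tokenize(s)]


class TestProteinFilter:
    @pytest.mark.parametrize("seq,ok", [
        ("MKTAYIAK", True),
        ("MKXTA", False),     # unknown residue X
        ("", False),
        ("MKTA*", False),
    ])
    def test_filter(self, seq, ok):
        assert filter_protein(seq) is ok

    def test_alphabet_is_22_letters_without_x(self):
        assert len(AMINO_ACIDS) == 22
        assert "X" not in AMINO_ACIDS
        assert len(SMILES_TOKENS) == 29


class TestCurate:
    def test_six_row_fixture_two_survivors(self, curation_fixture_table):
        pairs, ledger = curate(curation_fixture_table)
        assert ledger.n_in == 6
        assert len(pairs) == 2
        assert ledger.conserves
        assert ledger.dropped["label_zero"] == 3
        assert ledger.dropped["uncommon_atom"] == 1
        assert {p.target_id for p in pairs} == {"A", "B"}

    def test_structural_rules_each_account_in_ledger(self):
        # label-1 rows engineered to fail one structural rule apiece
        table = pd.DataFrame({
            "target_id": ["A"] * 2 + ["B"] * 2 + ["C"] * 2 + ["D"] * 2,
            "smiles": ["CCO", "C((", "CCN", "CCO", "CCC", "CC(C)O",
                       "CCO", "CCCO"],
            "sequence": ["MKT"] * 4 + ["MKXT"] * 2 + ["GAVL"] * 2,
            "activity": [1, 2, 1, 2, 1, 2, 1, 2],
        })
        pairs, ledger = curate(table)
        assert ledger.conserves
        assert ledger.dropped["invalid_smiles"] == 1     # A's survivor
        assert ledger.dropped["protein_rejected"] == 1   # C's survivor
        assert len(pairs) == 2                           # B's and D's

    def test_all_label_zero_rows_empty_output(self):
        table = pd.DataFrame({
            "target_id": ["A", "A"], "smiles": ["CCO", "CCN"],
            "sequence": ["MKT", "MKT"], "activity": [1.0, 1.0]})
        pairs, ledger = curate(table)
        assert pairs == [] and ledger.conserves
        assert ledger.dropped["label_zero"] == 2

    def test_missing_columns_raise(self):
        with pytest.raises(ValueError, match="missing columns"):
            curate(pd.DataFrame({"smiles": ["C"]}))

    def test_synthetic_corpus_is_filter_clean(self, small_corpus):
        """Fixtures never trip the SMILES or protein filters."""
        pairs, ledger = curate(small_corpus.to_frame())
        structural = sum(v for k, v in ledger.dropped.items()
                         if k != "label_zero")
        assert structural == 0
        assert ledger.conserves

    def test_idempotence(self, small_corpus):
        pairs, _ = curate(small_corpus.to_frame())
        table2 = pairs_to_frame(pairs)
        pairs2, ledger2 = curate(table2, keep_label_zero=True)
        dropped2 = {k: v for k, v in ledger2.dropped.items()
                    if k != "label_zero"}
        assert sum(dropped2.values()) == 0
        assert len(pairs2) == len(pairs)

    @given(st.lists(
        st.tuples(st.sampled_from(["A", "B"]),
                  st.sampled_from(["CCO", "C((", "[Si](C)C", "O=S(=O)(O)O"]),
                  st.sampled_from(["MKT", "MKX"]),
                  st.floats(0, 10, allow_nan=False)),
        min_size=0, max_size=25))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_ledger_always_conserves(self, rows):
        table = pd.DataFrame(rows, columns=["target_id", "smiles",
                                            "sequence", "activity"])
        if table.empty:
            table = pd.DataFrame(columns=["target_id", "smiles",
                                          "sequence", "activity"])
        pairs, ledger = curate(table)
        assert ledger.conserves
        assert ledger.n_out == len(pairs)
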