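import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import textindex as ti
from textindex.suffix import L_TYPE, S_TYPE


def encode(seqs):
    return ti.encode_collection(ti.StringCollection.from_strings(seqs))


class TestBruteForce:
    @pytest.mark.parametrize(
        "seqs, expected",
        [
            (["AB", "CA"], [6, 2, 5, 4, 0, 1, 3]),
            (["A"], [2, 1, 0]),
            (["", ""], [2, 0, 1]),
        ],
    )
    def test_known_orders(self, seqs, expected):
        assert ti.brute_force_sa(encode(seqs)).tolist() == expected

    def test_equal_suffixes_tie_broken_by_string_rank(self):
        # identical strings: equal content suffixes order by string index
        ct = encode(["AC", "AC"])
        sa = ti.brute_force_sa(ct)
        rows_of_A = [p for p in sa if ct.codes[p] == ord("A")]
        assert rows_of_A == [0, 3]  # string 1's "AC$..." before string 2's


class TestClassify:
    def test_single_string_all_l_before_sentinel(self, w2):
        m = ti.classify_ls_types(w2)
        assert m.types.tolist() == [L_TYPE, L_TYPE, S_TYPE]
        # the sentinel is S preceded by L, hence the only LMS position
        assert m.lms.tolist() == [2]

    def test_adjacent_separators_are_ascending(self):
        # "$ $" pairs: the left separator is the smaller symbol, so S
        ct = encode(["", ""])
        m = ti.classify_ls_types(ct)
        assert m.types.tolist() == [S_TYPE, L_TYPE, S_TYPE]
        assert m.lms.tolist() == [2]

    def test_definition_scan_matches_pairwise_order(self, corpus_results):
        # every position is S iff its suffix sorts before the next one
        for row in corpus_results[:40]:
            ct, sa = row["ct"], row["sa"]
            rank = np.empty(ct.N, dtype=np.int64)
            rank[sa] = np.arange(ct.N)
            m = ti.classify_ls_types(ct)
            for i in range(ct.N - 1):
                assert (m.types[i] == S_TYPE) == (rank[i] < rank[i + 1])

    def test_lms_positions_are_local_minima(self, w1):
        # position 4 ('A' followed by '$') is L-type, so only the first
        # separator and the sentinel are LMS in W1
        m = ti.classify_ls_types(w1)
        assert m.lms.tolist() == [2, 6]


class TestInducedSortPass:
    def test_seeded_from_correct_lms_completes_w1(self, w1):
        m = ti.classify_ls_types(w1)
        # sorted LMS suffixes of W1: positions 6 ($#...), 2, 4 sorted by suffix
        brute = ti.brute_force_sa(w1)
        rank = np.empty(w1.N, dtype=np.int64)
        rank[brute] = np.arange(w1.N)
        sorted_lms = sorted(m.lms.tolist(), key=lambda p: rank[p])
        seeded = ti.seed_from_sorted_lms(w1, np.array(sorted_lms))
        assert ti.induced_sort_pass(w1, m, seeded).tolist() == [6, 2, 5, 4, 0, 1, 3]

    def test_oracle_equivalence_on_random_instances(self, corpus_results):
        for row in corpus_results[:60]:
            ct = row["ct"]
            m = ti.classify_ls_types(ct)
            rank = np.empty(ct.N, dtype=np.int64)
            rank[row["brute"]] = np.arange(ct.N)
            sorted_lms = np.array(sorted(m.lms.tolist(), key=lambda p: rank[p]))
            out = ti.induced_sort_pass(ct, m, ti.seed_from_sorted_lms(ct, sorted_lms))
            assert np.array_equal(out, row["brute"])


class TestGsacaK:
    @pytest.mark.parametrize(
        "seqs, expected",
        [
            (["AB", "CA"], [6, 2, 5, 4, 0, 1, 3]),
            (["A"], [2, 1, 0]),
            (["", ""], [2, 0, 1]),
            ([""], [1, 0]),
            (["", "G", ""], [4, 0, 2, 3, 1]),
        ],
    )
    def test_small_collections(self, seqs, expected):
        ct = encode(seqs)
        assert ti.gsaca_k(ct).tolist() == expected
        assert ti.brute_force_sa(ct).tolist() == expected

    def test_structural_invariants(self, corpus_results):
        for row in corpus_results:
            ct, sa = row["ct"], row["sa"]
            ti.validate_suffix_array(ct, sa)  # permutation + sentinel + seps

    def test_determinism(self):
        ct = encode(["GATTACA", "TACAT", "GATTACA"])
        first = ti.gsaca_k(ct)
        for _ in range(3):
            assert np.array_equal(ti.gsaca_k(ct), first)

    def test_recursion_depth_is_logarithmic(self, corpus_results):
        from conftest import log2_bound

        for row in corpus_results:
            assert row["depth"] <= log2_bound(row["ct"].N)

    def test_deep_repetitive_input_forces_recursion(self):
        # a Fibonacci word is self-similar at every scale and drives
        # the naming step through several recursion levels
        a, b = "A", "AB"
        while len(b) < 400:
            a, b = b, b + a
        ct = encode([b])
        sa, stats = ti.gsaca_k(ct, return_stats=True)
        assert stats["max_depth"] >= 2
        assert np.array_equal(sa, ti.brute_force_sa(ct))

    @settings(deadline=None, max_examples=150)
    @given(
        st.lists(
            st.text(alphabet="AB", max_size=15), min_size=1, max_size=5
        )
    )
    def test_matches_brute_force_on_binary_collections(self, seqs):
        ct = encode(seqs)
        assert np.array_equal(ti.gsaca_k(ct), ti.brute_force_sa(ct))


class TestDistinctSeparatorReference:
    def test_remap_is_order_preserving(self, w1):
        codes, sigma = ti.suffix.remap_distinct_separators(w1)
        assert codes.tolist() == [67, 68, 1, 69, 67, 2, 0]
        assert sigma == w1.sigma + w1.d

    def test_reference_equals_gsaca(self, corpus_results):
        for row in corpus_results[:100]:
            assert np.array_equal(row["ref"], row["sa"])
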