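import numpy as np
import pytest

import textindex as ti


def encode(seqs):
    return ti.encode_collection(ti.StringCollection.from_strings(seqs))


class TestBwt:
    def test_w1_codes_and_rendering(self, w1):
        sa = ti.gsaca_k(w1)
        bwt = ti.bwt_from_sa(w1, sa)
        assert bwt.tolist() == [1, 66, 65, 67, 0, 65, 1]
        assert ti.render_bwt(bwt) == b"$BAC#A$"
        assert np.array_equal(ti.parse_rendered_bwt(b"$BAC#A$"), bwt)

    def test_w2_rendering(self, w2):
        assert ti.render_bwt(ti.bwt_from_sa(w2, ti.gsaca_k(w2))) == b"$A#"

    def test_wraparound_row_holds_end_marker(self, corpus_results):
        for row in corpus_results[:40]:
            ct, sa = row["ct"], row["sa"]
            bwt = ti.bwt_from_sa(ct, sa)
            i = int(np.flatnonzero(sa == 0)[0])
            assert bwt[i] == 0

    def test_multiset_conservation_and_scatter(self, corpus_results):
        for row in corpus_results[:60]:
            ct, sa = row["ct"], row["sa"]
            bwt = ti.bwt_from_sa(ct, sa)
            assert sorted(bwt.tolist()) == sorted(ct.codes.tolist())
            assert np.array_equal(ti.text_from_bwt(bwt, sa), ct.codes)


class TestInvertBwt:
    @pytest.mark.parametrize(
        "seqs", [["AB", "CA"], ["A"], ["", ""], ["BANANA", "ANA", ""]]
    )
    def test_recovers_multiset(self, seqs):
        ct = encode(seqs)
        bwt = ti.bwt_from_sa(ct, ti.gsaca_k(ct))
        rec = ti.invert_bwt(bwt, ct.d)
        assert sorted(rec) == sorted(s.encode() for s in seqs)

    def test_recovers_multiset_on_corpus(self, corpus_results):
        for row in corpus_results:
            bwt = ti.bwt_from_sa(row["ct"], row["sa"])
            assert sorted(ti.invert_bwt(bwt, row["ct"].d)) == sorted(row["coll"].seqs)

    def test_rejects_malformed(self):
        with pytest.raises(ValueError):
            ti.invert_bwt(np.array([1, 65, 1, 0]), d=1)  # two separators
        with pytest.raises(ValueError):
            ti.invert_bwt(np.array([65, 1]), d=1)  # no end-marker


class TestRankBitvector:
    def test_w1_bits_and_ranks(self, w1):
        bv = ti.build_separator_bitvector(w1)
        assert bv.bits.astype(int).tolist() == [0, 0, 1, 0, 0, 1, 0]
        assert bv.rank1(0) == 0
        assert bv.rank1(3) == 1
        assert bv.rank1(7) == 2

    def test_rank_is_exclusive_prefix_count(self):
        rng = np.random.default_rng(7)
        bits = rng.random(1000) < 0.3
        bv = ti.RankBitvector(bits)
        cum = np.concatenate(([0], np.cumsum(bits)))
        for p in range(0, 1001, 13):
            assert bv.rank1(p) == cum[p]
        ps = np.arange(1001)
        assert np.array_equal(bv.rank1_array(ps), cum)

    def test_word_boundary_sizes(self):
        for n in (63, 64, 65, 128):
            bits = np.ones(n, dtype=bool)
            bv = ti.RankBitvector(bits)
            assert bv.rank1(n) == n
            assert bv.rank1(n - 1) == n - 1


class TestDocumentArray:
    def test_w1_values(self, w1):
        sa = ti.gsaca_k(w1)
        assert ti.document_array(w1, sa).tolist() == [3, 1, 2, 2, 1, 1, 2]

    def test_w2_values(self, w2):
        assert ti.document_array(w2, ti.gsaca_k(w2)).tolist() == [2, 1, 1]

    def test_first_row_is_pseudo_string(self, corpus_results):
        for row in corpus_results[:80]:
            da = ti.document_array(row["ct"], row["sa"])
            assert da[0] == row["ct"].d + 1

    def test_direct_equals_light(self, corpus_results):
        for row in corpus_results:
            ct, sa = row["ct"], row["sa"]
            assert np.array_equal(
                ti.document_array(ct, sa, mode="direct"),
                ti.document_array(ct, sa, mode="light"),
            )


class TestGsa:
    def test_w1_pairs(self, w1):
        sa = ti.gsaca_k(w1)
        g = ti.gsa_from_sa_da(w1, sa, ti.document_array(w1, sa))
        assert list(zip(g.docs.tolist(), g.offs.tolist())) == [
            (3, 0), (1, 2), (2, 2), (2, 1), (1, 0), (1, 1), (2, 0),
        ]

    def test_w2_pairs(self, w2):
        sa = ti.gsaca_k(w2)
        g = ti.gsa_from_sa_da(w2, sa, ti.document_array(w2, sa))
        assert list(zip(g.docs.tolist(), g.offs.tolist())) == [(2, 0), (1, 1), (1, 0)]

    def test_string_one_offsets_equal_global_positions(self, corpus_results):
        for row in corpus_results[:40]:
            ct, sa = row["ct"], row["sa"]
            da = ti.document_array(ct, sa)
            g = ti.gsa_from_sa_da(ct, sa, da)
            mask = g.docs == 1
            assert np.array_equal(g.offs[mask], sa[mask])

    def test_round_trip_and_separator_offsets(self, corpus_results):
        for row in corpus_results[:60]:
            ct, sa = row["ct"], row["sa"]
            g = ti.gsa_from_sa_da(ct, sa, ti.document_array(ct, sa))
            for a, b, p in zip(g.docs, g.offs, sa):
                assert ti.local_to_global(ct, int(a), int(b)) == int(p)
            # the separator rows carry offset n_a
            for k, sep in enumerate(ct.sep_positions, start=1):
                i = int(np.flatnonzero(sa == sep)[0])
                assert (int(g.docs[i]), int(g.offs[i])) == (k, ct.length_of(k))
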