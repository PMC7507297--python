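"""Arrays derived from the suffix array: BWT, document array, GSA.

The BWT follows the classic identity ``BWT[i] = T[(SA[i] - 1) mod N]``.
The document array gives, for each suffix-array row, the 1-based index
of the string owning that suffix (``d + 1`` for the end-marker row, and
a separator belongs to the string it terminates).  It can be computed
directly from the string start table, or "lightweight" from a
separator-marking bitvector with constant-time rank:
``DA[i] = rank1(SA[i]) + 1`` with rank EXCLUSIVE of its argument — the
end-marker row requires counting only the separators strictly before
position N - 1, which forces the exclusive convention.

The generalized suffix array stores each row as a (string, offset)
pair.  Because ``sa[1..d]`` are the separator positions in string
order, string ``a >= 2`` starts at ``sa[a - 1] + 1``; offsets can be
read off either from that identity or from the start table, and the
two routes are cross-checked.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from . import _kernels as K
from .collection import ConcatText, END_MARKER, SEPARATOR, concat_from_codes

RENDER_END = ord("#")
RENDER_SEP = ord("$")


class IndexValidationError(ValueError):
    """A derived structure is inconsistent with its inputs."""


class GeneralizedSuffixArray(NamedTuple):
    docs: np.ndarray  # 1-based string index per row
    offs: np.ndarray  # local offset per row


# ---------------------------------------------------------------- BWT


def bwt_from_sa(ct: ConcatText, sa: np.ndarray) -> np.ndarray:
    """BWT codes: the symbol preceding each suffix, cyclically."""
    sa = np.asarray(sa, dtype=np.int64)
    return ct.codes[(sa - 1) % ct.N]


def render_bwt(bwt: np.ndarray) -> bytes:
    """Render BWT codes as bytes, with '#' and '$' for the markers."""
    out = np.asarray(bwt, dtype=np.int64).astype(np.uint8)
    out[np.asarray(bwt) == END_MARKER] = RENDER_END
    out[np.asarray(bwt) == SEPARATOR] = RENDER_SEP
    return out.tobytes()


def parse_rendered_bwt(data: bytes) -> np.ndarray:
    """Inverse of :func:`render_bwt` (assumes '#'/'$' are markers)."""
    arr = np.frombuffer(data, dtype=np.uint8).astype(np.int64)
    out = arr.copy()
    out[arr == RENDER_END] = END_MARKER
    out[arr == RENDER_SEP] = SEPARATOR
    return out


def text_from_bwt(bwt: np.ndarray, sa: np.ndarray) -> np.ndarray:
    """Scatter the BWT back onto text positions: T[(sa[i]-1) mod N] = bwt[i]."""
    bwt = np.asarray(bwt, dtype=np.int64)
    sa = np.asarray(sa, dtype=np.int64)
    n = sa.shape[0]
    codes = np.empty(n, dtype=np.int64)
    codes[(sa - 1) % n] = bwt
    return codes


def invert_bwt(bwt: np.ndarray, d: int) -> list[bytes]:
    """Recover the collection's strings (as a multiset) from the BWT.

    Stable LF-mapping walks start at each separator row of the first
    column and collect symbols backwards until the preceding symbol is
    again a separator or the end-marker.  With a single shared
    separator symbol the stable LF may pair strings with the "wrong"
    separator occurrence, so only the multiset of strings — not their
    order — is guaranteed.
    """
    bwt = np.asarray(bwt, dtype=np.int64)
    n = bwt.shape[0]
    if int(np.count_nonzero(bwt == END_MARKER)) != 1:
        raise ValueError("BWT must contain exactly one end-marker")
    if int(np.count_nonzero(bwt == SEPARATOR)) != d:
        raise ValueError(f"BWT must contain exactly {d} separators")
    order = np.argsort(bwt, kind="stable")  # F rank -> BWT row
    lf = np.empty(n, dtype=np.int64)
    lf[order] = np.arange(n, dtype=np.int64)
    # first-column rows 1..d hold the separator suffixes
    starts = np.arange(1, d + 1, dtype=np.int64)
    flat, bounds = K.lf_walk(bwt, starts, lf, n)
    out = []
    for w in range(d):
        piece = flat[bounds[w] : bounds[w + 1]]
        out.append(piece.astype(np.uint8).tobytes())
    if sum(len(s) for s in out) != n - d - 1:
        raise ValueError("LF walks did not consume every content symbol")
    return out


# ------------------------------------------------- separator bitvector


class RankBitvector:
    """Bit array with a word directory answering rank1 in O(1).

    ``rank1(p)`` counts ones among positions 0..p-1 (exclusive of p),
    for 0 <= p <= N.
    """

    _WORD = 64

    def __init__(self, bits: np.ndarray):
        bits = np.asarray(bits, dtype=bool)
        self.n = int(bits.shape[0])
        nwords = (self.n + self._WORD - 1) // self._WORD
        padded = np.zeros(max(nwords, 1) * self._WORD, dtype=np.uint8)
        padded[: self.n] = bits
        self._words = np.packbits(
            padded.reshape(-1, 8), axis=1, bitorder="little"
        ).reshape(-1).view(np.uint64)
        pops = np.bitwise_count(self._words).astype(np.int64)
        self._cum = np.concatenate(([0], np.cumsum(pops)))
        self.total = int(self._cum[-1])
        self.bits = bits

    def rank1(self, p: int) -> int:
        if not 0 <= p <= self.n:
            raise IndexError(f"rank argument {p} out of range 0..{self.n}")
        w, off = divmod(p, self._WORD)
        if w >= self._words.shape[0]:
            return self.total
        mask = np.uint64((1 << off) - 1)
        return int(self._cum[w]) + int(np.bitwise_count(self._words[w] & mask))

    def rank1_array(self, ps: np.ndarray) -> np.ndarray:
        ps = np.asarray(ps, dtype=np.int64)
        if ps.size and (ps.min() < 0 or ps.max() > self.n):
            raise IndexError("rank argument out of range")
        w = ps >> 6
        off = (ps & 63).astype(np.uint64)
        inside = w < self._words.shape[0]
        res = np.full(ps.shape, self.total, dtype=np.int64)
        wi = w[inside]
        masks = (np.uint64(1) << off[inside]) - np.uint64(1)
        res[inside] = self._cum[wi] + np.bitwise_count(
            self._words[wi] & masks
        ).astype(np.int64)
        return res


def build_separator_bitvector(ct: ConcatText) -> RankBitvector:
    """B[i] = 1 iff T[i] is a separator; rank1 is exclusive."""
    return RankBitvector(ct.codes == SEPARATOR)


# ------------------------------------------------------ document array


def document_array(ct: ConcatText, sa: np.ndarray, mode: str = "direct") -> np.ndarray:
    """1-based owning-string index per suffix-array row.

    ``mode='direct'`` locates each position in the start table;
    ``mode='light'`` uses the separator bitvector identity
    ``DA[i] = rank1(SA[i]) + 1``.  Both return identical arrays.
    """
    sa = np.asarray(sa, dtype=np.int64)
    if mode == "direct":
        return np.searchsorted(ct.starts, sa, side="right").astype(np.int64)
    if mode == "light":
        bv = build_separator_bitvector(ct)
        return bv.rank1_array(sa) + 1
    raise ValueError(f"unknown document-array mode {mode!r}")


# -------------------------------------------------------------- GSA


def gsa_from_sa_da(
    ct: ConcatText, sa: np.ndarray, da: np.ndarray
) -> GeneralizedSuffixArray:
    """(string, offset) pairs for every suffix-array row.

    Offsets come from the separator-prefix identity (string ``a >= 2``
    starts at ``sa[a - 1] + 1``) and are cross-checked against the
    start table; separator rows carry ``b = n_a`` and the end-marker
    row is ``(d + 1, 0)``.
    """
    sa = np.asarray(sa, dtype=np.int64)
    da = np.asarray(da, dtype=np.int64)
    d = ct.d
    start_of = np.empty(d + 2, dtype=np.int64)
    start_of[1] = 0
    start_of[2 : d + 2] = sa[1 : d + 1] + 1
    offs = sa - start_of[da]
    offs_by_table = sa - ct.starts[da - 1]
    bad = np.flatnonzero(offs != offs_by_table)
    if bad.size:
        i = int(bad[0])
        raise IndexValidationError(
            f"GSA offset disagreement at row {i}: separator-prefix route "
            f"gives {int(offs[i])}, start-table route gives "
            f"{int(offs_by_table[i])}"
        )
    if offs.size and int(offs.min()) < 0:
        i = int(np.flatnonzero(offs < 0)[0])
        raise IndexValidationError(f"negative GSA offset at row {i}")
    return GeneralizedSuffixArray(docs=da.copy(), offs=offs)
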