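"""Suffix-array construction for string collections by induced sorting.

The target order is lexicographic with every separator occurrence
treated as a distinct symbol increasing with text position, so equal
suffixes from different strings are tie-broken by string rank.  Under
that order the suffix array always starts with the end-marker suffix
(``sa[0] = N - 1``) followed by the ``d`` separator suffixes in text
order (``sa[1..d] = sep_positions``).

Three routes to the same order are provided:

* :func:`gsaca_k` — the production path: SA-IS-style induced sorting on
  the shared-separator encoding, with the separator bucket pre-placed
  in text order and excluded from the induction sweeps, and fresh names
  for any LMS substring touching a separator.  Linear time in N.
* :func:`sa_via_distinct_separators` — a reference: remap each
  separator occurrence to its own ascending code and run plain SA-IS.
* :func:`brute_force_sa` — a comparison sort oracle for small inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels as K
from .collection import ConcatText

L_TYPE = K.L_TYPE
S_TYPE = K.S_TYPE


@dataclass
class LSTypeMap:
    """Per-position L/S marks plus the LMS positions in text order."""

    types: np.ndarray  # uint8, 0 = L, 1 = S
    lms: np.ndarray  # increasing text positions


def classify_ls_types(ct: ConcatText) -> LSTypeMap:
    """Classify each position L or S under the separator-aware order.

    A position is S iff its suffix is smaller than the next one; for two
    adjacent separators the left occurrence is the smaller symbol, so it
    is S-type.  LMS positions are S positions preceded by an L position.
    """
    types = K.classify(ct.codes, True)
    lms = np.flatnonzero((types[1:] == S_TYPE) & (types[:-1] == L_TYPE)) + 1
    return LSTypeMap(types=types, lms=lms)


def remap_distinct_separators(ct: ConcatText) -> tuple[np.ndarray, int]:
    """Give each separator occurrence its own code.

    Returns ``(codes', sigma')`` with end-marker -> 0, the k-th
    separator (1-based) -> k, and content code c -> c + d.  Plain
    lexicographic order on the remapped text equals the separator-aware
    order on the original.
    """
    d = ct.d
    out = np.where(ct.codes >= 2, ct.codes + d, np.int64(0))
    out[ct.sep_positions] = np.arange(1, d + 1, dtype=np.int64)
    return out, ct.sigma + d


def brute_force_sa(ct: ConcatText) -> np.ndarray:
    """Comparison-sort oracle: O(N^2 log N), ground truth for tests."""
    codes, _ = remap_distinct_separators(ct)
    key = tuple(int(c) for c in codes)
    order = sorted(range(ct.N), key=lambda i: key[i:])
    return np.asarray(order, dtype=np.int64)


def _sais(text: np.ndarray, sigma: int, depth: int, stats: dict) -> np.ndarray:
    """Plain SA-IS on a text whose last symbol is the unique minimum."""
    n = text.shape[0]
    stats["max_depth"] = max(stats["max_depth"], depth)
    sa = np.full(n, -1, dtype=np.int64)
    if n == 1:
        sa[0] = 0
        return sa
    if n == 2:
        sa[0], sa[1] = 1, 0
        return sa
    types = K.classify(text, False)
    counts = K.bucket_counts(text, sigma)
    lms = np.flatnonzero((types[1:] == S_TYPE) & (types[:-1] == L_TYPE)) + 1
    # phase 1: sort the LMS substrings by one full induction round
    K.seed_lms_tails(sa, text, counts, lms, False)
    K.induce_l(sa, text, types, counts, False)
    K.induce_s(sa, text, types, counts, False)
    lms_sorted = np.empty(lms.shape[0], dtype=np.int64)
    k = K.collect_lms_in_order(sa, types, lms_sorted)
    assert k == lms.shape[0]
    # phase 2: name them; recurse while names collide
    name_of = np.full(n, -1, dtype=np.int64)
    num_names = K.name_lms(text, types, lms_sorted, name_of, False)
    if num_names < lms.shape[0]:
        reduced = name_of[lms]
        red_sa = _sais(reduced, num_names, depth + 1, stats)
        lms_sorted = lms[red_sa]
    else:
        lms_sorted = np.empty_like(lms)
        lms_sorted[name_of[lms]] = lms
    # phase 3: induce the full order from the sorted LMS suffixes
    sa.fill(-1)
    K.seed_lms_tails(sa, text, counts, lms_sorted, False)
    K.induce_l(sa, text, types, counts, False)
    K.induce_s(sa, text, types, counts, False)
    return sa


def sais(text: np.ndarray, sigma: int | None = None) -> np.ndarray:
    """Suffix array of a single text ending in a unique smallest sentinel."""
    text = np.ascontiguousarray(text, dtype=np.int64)
    if sigma is None:
        sigma = int(text.max()) + 1
    return _sais(text, sigma, 0, {"max_depth": 0})


def sa_via_distinct_separators(ct: ConcatText) -> np.ndarray:
    """Reference construction: distinct-separator remap + plain SA-IS."""
    codes, sigma = remap_distinct_separators(ct)
    return sais(codes, sigma)


def _seed_final(ct: ConcatText, counts: np.ndarray, sorted_lms: np.ndarray) -> np.ndarray:
    """Seed array for the final induction: sentinel and separators at
    their known final slots, sorted content LMS at bucket tails."""
    sa = np.full(ct.N, -1, dtype=np.int64)
    sa[0] = ct.N - 1
    sa[1 : 1 + ct.d] = ct.sep_positions
    K.seed_lms_tails(sa, ct.codes, counts, sorted_lms, True)
    return sa


def seed_from_sorted_lms(ct: ConcatText, sorted_lms: np.ndarray) -> np.ndarray:
    """Public seeding helper for :func:`induced_sort_pass`."""
    counts = K.bucket_counts(ct.codes, ct.sigma)
    return _seed_final(ct, counts, np.asarray(sorted_lms, dtype=np.int64))


def induced_sort_pass(
    ct: ConcatText, types: LSTypeMap, seeded: np.ndarray
) -> np.ndarray:
    """Run the two induction sweeps over a seeded partial suffix array.

    ``seeded`` must hold the end-marker at slot 0, the separators in
    text order at slots 1..d, and the correctly ordered LMS positions
    at their bucket tails; every other slot is -1.  The sweeps never
    write into the separator bucket.
    """
    sa = np.array(seeded, dtype=np.int64, copy=True)
    counts = K.bucket_counts(ct.codes, ct.sigma)
    K.induce_l(sa, ct.codes, types.types, counts, True)
    K.induce_s(sa, ct.codes, types.types, counts, True)
    if np.any(sa < 0):
        raise AssertionError(
            "induction left empty slots; the seeding violates its contract"
        )
    return sa


def gsaca_k(ct: ConcatText, return_stats: bool = False):
    """Suffix array of the concatenated collection, separator-aware order.

    SA-IS / SACA-K-style construction adapted to collections: the
    separator suffixes' relative order is known a priori (text order),
    so they are pre-placed and shielded from the induction sweeps, and
    LMS substrings containing a separator always receive fresh names —
    issued in separator text order, which realizes rank tie-breaking.
    Runs in O(N) for constant alphabet size.
    """
    n = ct.N
    stats = {"max_depth": 0}
    text = ct.codes
    types = K.classify(text, True)
    counts = K.bucket_counts(text, ct.sigma)
    lms = np.flatnonzero((types[1:] == S_TYPE) & (types[:-1] == L_TYPE)) + 1
    # phase 1: pre-place sentinel + separators, sort content LMS substrings
    sa = np.full(n, -1, dtype=np.int64)
    sa[0] = n - 1
    sa[1 : 1 + ct.d] = ct.sep_positions
    K.seed_lms_tails(sa, text, counts, lms, True)
    K.induce_l(sa, text, types, counts, True)
    K.induce_s(sa, text, types, counts, True)
    lms_sorted = np.empty(lms.shape[0], dtype=np.int64)
    k = K.collect_lms_in_order(sa, types, lms_sorted)
    assert k == lms.shape[0]
    # phase 2: name LMS substrings; separator-touching ones get fresh names
    name_of = np.full(n, -1, dtype=np.int64)
    num_names = K.name_lms(text, types, lms_sorted, name_of, True)
    if num_names < lms.shape[0]:
        reduced = name_of[lms]
        red_sa = _sais(reduced, num_names, 1, stats)
        lms_sorted = lms[red_sa]
    else:
        lms_sorted = np.empty_like(lms)
        lms_sorted[name_of[lms]] = lms
    # phase 3: final induction from the fully sorted LMS suffixes
    sa = _seed_final(ct, counts, lms_sorted)
    K.induce_l(sa, text, types, counts, True)
    K.induce_s(sa, text, types, counts, True)
    if return_stats:
        return sa, stats
    return sa


def validate_suffix_array(ct: ConcatText, sa: np.ndarray) -> None:
    """Cheap structural checks: permutation, sentinel first, separators
    in text order right after it."""
    sa = np.asarray(sa)
    if sa.shape[0] != ct.N or np.bincount(sa, minlength=ct.N).max() != 1:
        raise ValueError("suffix array is not a permutation of 0..N-1")
    if sa[0] != ct.N - 1:
        raise ValueError("sa[0] must be the end-marker position N-1")
    if not np.array_equal(sa[1 : 1 + ct.d], ct.sep_positions):
        raise ValueError("sa[1..d] must list the separator positions ascending")
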