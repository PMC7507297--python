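"""Numba kernels for induced suffix sorting.

All kernels work on int64 code arrays.  ``types`` marks each position
L (0) or S (1).  ``sep_aware`` / ``skip_sep`` implement the separator
convention for multi-string sorting: separator occurrences (code 1)
compare as pairwise distinct symbols increasing with text position, so
the generalized driver pre-places all separator suffixes in text order
and the induction sweeps must never write into the code-1 bucket.
"""

from __future__ import annotations

import numpy as np
from numba import njit

L_TYPE = 0
S_TYPE = 1


@njit(cache=True)
def classify(text, sep_aware):
    """Right-to-left L/S classification.

    Under the separator-aware order two adjacent equal separators are
    an ascending pair, so the left one is S-type unconditionally.
    """
    n = text.shape[0]
    types = np.empty(n, np.uint8)
    types[n - 1] = S_TYPE
    for i in range(n - 2, -1, -1):
        if text[i] < text[i + 1]:
            types[i] = S_TYPE
        elif text[i] > text[i + 1]:
            types[i] = L_TYPE
        elif sep_aware and text[i] == 1:
            types[i] = S_TYPE
        else:
            types[i] = types[i + 1]
    return types


@njit(cache=True)
def bucket_counts(text, sigma):
    counts = np.zeros(sigma, np.int64)
    for i in range(text.shape[0]):
        counts[text[i]] += 1
    return counts


@njit(cache=True)
def seed_lms_tails(sa, text, counts, lms, skip_sep):
    """Place LMS positions at their bucket tails, last to first.

    If ``lms`` is sorted by suffix order this preserves that order
    inside each bucket.  With ``skip_sep`` set, sentinel and separator
    positions (codes 0 and 1) are assumed pre-placed and skipped.
    """
    tails = np.cumsum(counts)
    for idx in range(lms.shape[0] - 1, -1, -1):
        p = lms[idx]
        c = text[p]
        if skip_sep and c <= 1:
            continue
        tails[c] -= 1
        sa[tails[c]] = p


@njit(cache=True)
def induce_l(sa, text, types, counts, skip_sep):
    """Left-to-right sweep inducing L-suffixes at bucket heads."""
    n = text.shape[0]
    heads = np.empty_like(counts)
    acc = 0
    for c in range(counts.shape[0]):
        heads[c] = acc
        acc += counts[c]
    for i in range(n):
        j = sa[i]
        if j > 0:
            k = j - 1
            if types[k] == L_TYPE:
                c = text[k]
                if skip_sep and c == 1:
                    continue
                sa[heads[c]] = k
                heads[c] += 1


@njit(cache=True)
def induce_s(sa, text, types, counts, skip_sep):
    """Right-to-left sweep inducing S-suffixes at bucket tails."""
    n = text.shape[0]
    tails = np.cumsum(counts)
    for i in range(n - 1, -1, -1):
        j = sa[i]
        if j > 0:
            k = j - 1
            if types[k] == S_TYPE:
                c = text[k]
                if skip_sep and c == 1:
                    continue
                tails[c] -= 1
                sa[tails[c]] = k


@njit(cache=True)
def collect_lms_in_order(sa, types, out):
    """Gather LMS positions as they appear in ``sa``; returns the count."""
    k = 0
    for i in range(sa.shape[0]):
        j = sa[i]
        if j > 0 and types[j] == S_TYPE and types[j - 1] == L_TYPE:
            out[k] = j
            k += 1
    return k


@njit(cache=True)
def _lms_equal(text, types, a, b, sep_aware):
    """Whether the LMS substrings starting at a and b are equal.

    With ``sep_aware`` a substring touching a separator is never equal
    to another occurrence: separators are pairwise-distinct symbols.
    """
    n = text.shape[0]
    if a == n - 1 or b == n - 1:
        return a == b
    i = 0
    while True:
        pa = a + i
        pb = b + i
        if text[pa] != text[pb]:
            return False
        if sep_aware and text[pa] <= 1:
            return False
        if i > 0:
            a_lms = types[pa] == S_TYPE and types[pa - 1] == L_TYPE
            b_lms = types[pb] == S_TYPE and types[pb - 1] == L_TYPE
            if a_lms and b_lms:
                return True
            if a_lms != b_lms:
                return False
        i += 1


@njit(cache=True)
def name_lms(text, types, lms_sorted, name_of, sep_aware):
    """Assign names to LMS substrings in sorted order; returns name count."""
    name_of[lms_sorted[0]] = 0
    cur = 0
    prev = lms_sorted[0]
    for idx in range(1, lms_sorted.shape[0]):
        p = lms_sorted[idx]
        if not _lms_equal(text, types, prev, p, sep_aware):
            cur += 1
        name_of[p] = cur
        prev = p
    return cur + 1


@njit(cache=True)
def kasai_capped(text, sa):
    """Permuted-LCP sweep with matches stopped at codes < 2.

    Capping at separators is exactly the plain LCP of the text in which
    every separator occurrence is a distinct symbol, which is the order
    the suffix array realizes, so the h - 1 carry of the classic sweep
    remains valid.
    """
    n = text.shape[0]
    rank = np.empty(n, np.int64)
    for i in range(n):
        rank[sa[i]] = i
    lcp = np.zeros(n, np.int64)
    h = 0
    for i in range(n):
        r = rank[i]
        if r > 0:
            j = sa[r - 1]
            while i + h < n and j + h < n and text[i + h] == text[j + h] and text[i + h] >= 2:
                h += 1
            lcp[r] = h
            if h > 0:
                h -= 1
        else:
            h = 0
    return lcp


@njit(cache=True)
def lf_walk(bwt, starts, lf, limit):
    """Backward LF walks from given rows, stopping at codes < 2.

    Returns a flat array of collected codes (reversed per walk) and the
    walk boundaries.
    """
    total = 0
    n = bwt.shape[0]
    buf = np.empty(n, np.int64)
    bounds = np.empty(starts.shape[0] + 1, np.int64)
    bounds[0] = 0
    for w in range(starts.shape[0]):
        r = starts[w]
        steps = 0
        begin = total
        while steps <= limit:
            c = bwt[r]
            if c < 2:
                break
            buf[total] = c
            total += 1
            r = lf[r]
            steps += 1
        # reverse in place: the walk collected the string back to front
        lo = begin
        hi = total - 1
        while lo < hi:
            tmp = buf[lo]
            buf[lo] = buf[hi]
            buf[hi] = tmp
            lo += 1
            hi -= 1
        bounds[w + 1] = total
    return buf[:total], bounds
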