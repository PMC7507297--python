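"""Separator-capped LCP array construction.

The LCP between two suffixes counts matching symbol pairs only while
both symbols are content (code >= 2): a separator or end-marker never
matches anything, not even another separator.  This is exactly the
plain LCP of the text in which every separator occurrence is its own
symbol — the same convention the suffix array order uses — so LCP
values never reach a separator and never cross string boundaries.
"""

from __future__ import annotations

import numpy as np

from . import _kernels as K
from .collection import MIN_CONTENT, ConcatText
from .suffix import validate_suffix_array


def capped_lcp(ct: ConcatText, p: int, q: int) -> int:
    """Longest common prefix of the suffixes at p and q, capped so the
    match stops strictly before any code < 2."""
    codes = ct.codes
    n = ct.N
    if not (0 <= p < n and 0 <= q < n):
        raise IndexError("positions out of range")
    h = 0
    while codes[p + h] == codes[q + h] and codes[p + h] >= MIN_CONTENT:
        h += 1
    return h


def lcp_from_sa(ct: ConcatText, sa: np.ndarray) -> np.ndarray:
    """LCP array over the suffix array, ``lcp[0] = 0``.

    Linear-time permuted-LCP sweep (the classic rank/Phi scheme) with
    the capped matching predicate.
    """
    validate_suffix_array(ct, sa)
    return K.kasai_capped(ct.codes, np.ascontiguousarray(sa, dtype=np.int64))


def brute_force_lcp(ct: ConcatText, sa: np.ndarray) -> np.ndarray:
    """Oracle: capped LCP of each consecutive suffix pair, directly."""
    n = ct.N
    lcp = np.zeros(n, dtype=np.int64)
    for i in range(1, n):
        lcp[i] = capped_lcp(ct, int(sa[i]), int(sa[i - 1]))
    return lcp
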