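# textindex

Suffix array, LCP array, Burrows–Wheeler transform, document array and
generalized suffix array construction for **string collections**, as a
Python library with a thin command-line front end.

Many sequence-analysis tasks — suffix–prefix overlap detection for
assembly, repeat finding, cDNA clustering, full-text indexing — start
from a suffix array built over a whole collection of reads, proteins or
documents rather than a single string. Concatenating the collection and
running a single-string construction either inflates the alphabet (one
sentinel per string) or silently compares suffixes across string
boundaries. This package builds the index directly for collections,
with well-defined cross-string semantics, and serializes every
structure in a documented binary layout.

## The model

A collection of `d` strings `T¹ … Tᵈ` over ASCII is concatenated as

```
T[0 .. N-1] = T¹ $ T² $ … Tᵈ $ #        N = Σ (nᵢ + 1) + 1
```

with a single separator symbol `$` (internal code 1) and end-marker `#`
(code 0), both smaller than every content symbol. Suffixes are compared
lexicographically under one extra rule: **separator occurrences behave
as pairwise-distinct symbols increasing with text position**, so equal
suffixes from different strings are tie-broken by string rank and the
order is total. Under this order:

- `SA` is the permutation of `[0, N-1]` listing all suffixes ascending;
  `SA[0] = N-1` and `SA[1..d]` are the separator positions in string
  order.
- `LCP[i]` is the longest common prefix of rows `i-1` and `i`, **capped**
  so a match never includes a separator or the end-marker (`LCP[0]=0`).
- `BWT[i] = T[(SA[i] − 1) mod N]`.
- `DA[i]` is the 1-based string owning row `i`'s suffix (`d+1` for the
  end-marker row); the lightweight variant reads it from a separator
  bitvector `B` with constant-time rank as `DA[i] = rank₁(SA[i]) + 1`
  (rank exclusive of its argument).
- `GSA[i] = (a, b)` rewrites row `i` as string index plus local offset,
  using the fact that string `a ≥ 2` starts at `SA[a-1] + 1`.

Construction is SA-IS–style induced sorting adapted to collections:
separator suffixes are pre-placed in their known (text) order and
shielded from the induction sweeps, and any LMS substring touching a
separator receives a fresh name, so the recursion never merges suffixes
from different strings. Time is `O(N)`; the hot loops are numba-compiled
and a ~10 MB collection (10,000 × 1,000 DNA) builds all five structures
in seconds.

## Worked example

```python
import textindex as ti

ct = ti.encode_collection(ti.StringCollection.from_strings(["AB", "CA"]))
sa  = ti.gsaca_k(ct)                       # [6 2 5 4 0 1 3]
lcp = ti.lcp_from_sa(ct, sa)               # [0 0 0 0 1 0 0]
da  = ti.document_array(ct, sa)            # [3 1 2 2 1 1 2]
bwt = ti.bwt_from_sa(ct, sa)
ti.render_bwt(bwt)                         # b'$BAC#A$'
g   = ti.gsa_from_sa_da(ct, sa, da)        # (3,0) (1,2) (2,2) (2,1) (1,0) (1,1) (2,0)
```

Here `T = AB$CA$#` (N = 7). Row 0 is the end-marker suffix, owned by
pseudo-string `d+1 = 3`; rows 1–2 are the two separator suffixes in
string order; row 4 is `AB$CA$#` itself, sharing a 1-symbol prefix
(`A`) with the previous row `A$#` — the capped LCP stops before the
separator. `examples/` contains runnable scripts printing exactly these
tables, plus BWT inversion and the bitvector document array.

From a shell:

```bash
textindex build reads.fa --sa --lcp --gsa --bwt -o reads    # writes reads.sa, reads.lcp, ...
textindex check reads                                        # reloads and re-validates everything
```

Arrays are stored headerless, little-endian, 4 bytes per integer by
default (`--width 8` for N ≥ 2³²); the BWT as raw bytes with literal
`#`/`$`; the GSA as two parallel files `.gsa.doc` / `.gsa.off`.

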