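# Methods

## Text model and encoding

A collection of `d` byte strings is concatenated as
`T = T¹ $ T² $ … Tᵈ $ #` with the end-marker `#` encoded 0 and every
separator `$` encoded 1. Content bytes keep their raw values (printable
ASCII ≥ 32), so content codes are ≥ 2, encoding is trivially
reversible, and bucket arrays stay ≤ 256 entries; no dense alphabet
remapping is performed. Inputs containing bytes 0 or 1 are rejected.
Empty strings are legal and produce adjacent separators; every
algorithm below handles them without special cases. Coordinates are
0-based and half-open; `(a, b)` string/offset pairs are 1-based in `a`,
with `b = n_a` addressing the separator that ends string `a` and
`(d+1, 0)` addressing the end-marker.

## The suffix order

Suffixes are compared symbol-by-symbol with `# < $ < content`, plus one
rule that makes the order total: two separator occurrences compare by
text position. This is exactly the order obtained by remapping the k-th
separator to a k-th distinct symbol between `#` and the content
alphabet, and it implements tie-breaking of equal suffixes from
different strings by string rank. Consequences used throughout:
`SA[0] = N−1`, `SA[1..d]` = separator positions ascending, and two
suffixes both starting at separators share no prefix.

## Induced sorting with a shared separator

`gsaca_k` is SA-IS/SACA-K-style induced sorting run directly on the
shared-separator encoding (alphabet stays ≤ 256 regardless of `d`),
with three modifications that realize the order above:

1. **L/S classification**: adjacent equal separators are an ascending
   pair, so the left one is S-type unconditionally.
2. **Separator bucket pre-placement**: the relative order of all
   separator suffixes is known a priori (text order), so the sentinel
   and the `d` separator positions are written into `SA[0..d]` before
   each induction round, and both sweeps skip any induction targeting
   code 1. Inducing *from* those rows proceeds normally. This replaces
   the within-bucket L-before-S layout, which does not hold for the
   separator bucket (its single L-type suffix, `$#`, is the *largest*
   separator suffix).
3. **Naming**: an LMS substring that touches a separator is never equal
   to another occurrence, so each gets a fresh name. Because the
   separator bucket is pre-placed in text order and the sweeps are
   stable within equal symbols, identical-content substrings ending at
   different separators come out of phase 1 in separator text order,
   and fresh names issued in scan order are automatically consistent
   with rank tie-breaking.

Names that do collide belong to separator-free substrings, so the
recursion is plain SA-IS on the reduced name string (its last symbol,
the end-marker's name 0, is the unique minimum). Recursion depth is
bounded by `log₂ N` since each level at most halves the problem; the
observed depth on random DNA at N ≈ 10⁷ is 2. The `O(σ)` working-space
trick of the original formulation (reusing SA slots for bucket
counters) is deliberately not reproduced — plain count arrays are used;
the output order, not the space bound, is the contract here.

Two independent checks accompany the production path: a brute-force
comparison sort under the augmented order (the test oracle), and plain
SA-IS on the distinct-separator remapping (`d` extra symbols), which is
the semantic definition of the order. All three must agree exactly; the
test corpus (below) enforces this on every instance.

## Capped LCP

`LCP[i]` counts matching symbol pairs between rows `i−1` and `i` only
while both symbols are content (code ≥ 2): separators and the
end-marker never match anything, including themselves, so LCP values
never reach a separator and never span a string boundary. This equals
the plain LCP of the distinct-separator remapping, whose order is the
suffix-array order — which is why the classic linear-time permuted-LCP
sweep (rank/Φ with the `h − 1` carry) remains valid with the capped
matching predicate. LCP is computed post hoc from the finished suffix
array rather than interleaved with construction; the output contract is
identical and the decoupling keeps each stage independently testable.
The reading of the cap chosen here is strict: the separator position
itself is never counted as part of a match.

## Derived arrays

- **BWT**: `BWT[i] = T[(SA[i] − 1) mod N]`, vectorized. Text rendering
  writes literal `#` and `$`; text-mode *inputs* containing those two
  characters are rejected at read time so the rendering stays
  unambiguous (FASTA/FASTQ alphabets do not collide in practice).
- **Inversion** (verification utility): a stable LF mapping is built by
  a stable argsort of the BWT; one backward walk starts at each
  separator row of the first column and collects symbols until the
  preceding symbol is again a separator or the end-marker. With a
  single shared separator symbol the stable LF may attach a string to a
  different separator occurrence than the one that produced it, so
  inversion guarantees recovery of the string **multiset**, not the
  original order; the walks jointly consume every content symbol, which
  is asserted.
- **Document array**: direct mode is a binary search of `SA[i]` in the
  string start table; light mode is `DA[i] = rank₁(SA[i]) + 1` over the
  separator bitvector. Rank is **exclusive** of its argument — this is
  forced, not a convention choice: the end-marker row must satisfy
  `DA[0] = d + 1 = rank₁(N−1) + 1`, which requires counting only the
  `d` separators strictly before `N−1`. The bitvector packs bits into
  64-bit words with a cumulative-popcount directory (O(1) per query,
  ~1.02 bits per text position).
- **GSA**: `docs[i] = DA[i]`; `offs[i] = SA[i] − start(DA[i])` with
  `start(1) = 0` and `start(a) = SA[a−1] + 1` for `a ≥ 2`, exploiting
  that `SA[1..d]` are the separators in string order. A second route
  reads `start` from the encoding's start table; both are computed and
  any disagreement raises, naming the first offending row. Separator
  rows carry `b = n_a` and the end-marker row `(d+1, 0)`, extending the
  `(a, b)` convention to all `N` rows consistently with `DA[0] = d+1`.

## Serialization

Arrays are stored headerless: little-endian fixed-width unsigned
integers, 4 bytes per value by default, 8 when values can reach `2³²`,
one homogeneous array per file (`.sa`, `.lcp`, `.da`, `.gsa.doc`,
`.gsa.off`); the BWT as raw rendered bytes; plus an optional
human-readable tab-separated dump. Writing refuses (never truncates) on
width overflow, naming the first offending index. `check` reloads a
prefix, reconstructs the text by scattering the BWT along the suffix
array, rebuilds every structure from scratch and compares — so a single
corrupted byte in any file is caught without keeping the original
input around.

## Synthetic data

The generator draws each symbol independently and uniformly from a
chosen alphabet — the standard construction for random-DNA (4 letters)
and random-protein (25-letter IUPAC, A–Z without J) benchmark corpora —
plus a 2-letter and a 90-character printable-ASCII alphabet to stress
both ends of the alphabet range. String lengths are fixed or uniform on
an inclusive range; each fixture uses its own explicitly seeded RNG
stream. The canonical oracle corpus is 500 instances (seeds 0–499)
cycling string counts {1, 2, 4, 8} and the four alphabets with lengths
uniform on 0–40; every 4th instance permits empty strings, placed on
the d = 8 cycle so adjacent separators actually occur. What this corpus
does **not** emulate: the long shared prefixes of real read sets, real
protein composition bias, or document-scale inputs — uniform random
strings have short LCPs, so passing it demonstrates order/identity
correctness, not performance on adversarially repetitive data (the
Fibonacci-word and periodic-string unit tests cover deep recursion
separately).

## Sizes and numerical choices

The scalability condition is exercised at 10,000 strings of length
1,000 (N = 10,010,001, ~10 MB), which builds all five structures in
roughly ten seconds on one core with the numba kernels; indices are
int64 end to end in memory, independent of the on-disk width. Tests
compare arrays exactly — there are no tolerances anywhere in the
package; every check is equality of integer arrays or multisets.

## Known limitations

- Single-byte alphabets only; no Unicode, no dense remapping.
- BWT inversion guarantees multiset recovery only (see above).
- The 2⁶⁴-scale engineering envelope of C implementations (and their
  exact memory footprint) is out of scope; `--width 8` covers large
  outputs but everything is held in memory during construction.
- FASTQ qualities are discarded; the indexes are over sequences only.
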