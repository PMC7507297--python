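"""Random string-collection generators for tests and benchmarks.

Collections are drawn symbol-by-symbol with even sampling probability
over a chosen alphabet — the standard construction for random DNA
(4-letter) and random protein (25-letter IUPAC) corpora — plus a
2-letter and a 90-character printable-ASCII alphabet for stressing
small and large alphabets.  Generation is deterministic per seed, with
one private RNG stream per fixture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .collection import StringCollection

#: 25-letter IUPAC amino-acid alphabet (A..Z without J).
PROTEIN25 = b"ABCDEFGHIKLMNOPQRSTUVWXYZ"

ALPHABETS: dict[str, bytes] = {
    "binary": b"AB",
    "dna": b"ACGT",
    "protein": PROTEIN25,
    "ascii90": bytes(range(33, 123)),  # '!'..'z', 90 printable characters
}


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one reproducible random collection.

    ``length`` is either a fixed int or an inclusive ``(lo, hi)`` range
    sampled uniformly per string; with ``allow_empty`` unset the lower
    bound is clamped to 1.
    """

    d: int
    length: int | tuple[int, int] = (1, 40)
    alphabet: str = "dna"
    seed: int = 0
    allow_empty: bool = False


def generate_collection(spec: FixtureSpec) -> StringCollection:
    """Draw ``spec.d`` strings, each symbol uniform over the alphabet."""
    alpha = ALPHABETS.get(spec.alphabet)
    if alpha is None:
        alpha = spec.alphabet.encode("latin-1") if isinstance(spec.alphabet, str) else bytes(spec.alphabet)
    if len(alpha) == 0:
        raise ValueError("alphabet must not be empty")
    alpha_arr = np.frombuffer(alpha, dtype=np.uint8)
    rng = np.random.default_rng(spec.seed)
    if isinstance(spec.length, tuple):
        lo, hi = spec.length
        if not spec.allow_empty:
            lo = max(lo, 1)
        lengths = rng.integers(lo, hi + 1, size=spec.d)
    else:
        lengths = np.full(spec.d, spec.length, dtype=np.int64)
    total = int(lengths.sum())
    symbols = alpha_arr[rng.integers(0, alpha_arr.size, size=total)]
    seqs = []
    pos = 0
    for n in lengths:
        seqs.append(symbols[pos : pos + int(n)].tobytes())
        pos += int(n)
    ids = [f"seq{i + 1}" for i in range(spec.d)]
    return StringCollection(ids=ids, seqs=seqs)


_CORPUS_D = (1, 2, 4, 8)
_CORPUS_ALPHABETS = ("binary", "dna", "protein", "ascii90")


def oracle_corpus() -> list[tuple[FixtureSpec, StringCollection]]:
    """The canonical 500-instance corpus used by every oracle suite.

    Seeds 0..499 cycle over d in {1, 2, 4, 8} and the four alphabets,
    lengths uniform on 0..40; every 4th instance (the d = 8 ones, so
    adjacent separators actually occur) permits empty strings.
    """
    out = []
    for seed in range(500):
        spec = FixtureSpec(
            d=_CORPUS_D[seed % 4],
            length=(0, 40),
            alphabet=_CORPUS_ALPHABETS[(seed // 4) % 4],
            seed=seed,
            allow_empty=(seed % 4 == 3),
        )
        out.append((spec, generate_collection(spec)))
    return out
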