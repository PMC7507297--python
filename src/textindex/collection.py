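"""Encoded concatenation of a string collection.

A collection of ``d`` strings ``T^1 .. T^d`` is packed into a single
integer-coded text ``T[0 .. N-1] = T^1 $ T^2 $ ... T^d $ #`` where the
end-marker ``#`` (code 0) and the separator ``$`` (code 1) are reserved
codes smaller than every content symbol.  Content bytes keep their raw
values, so every content code is >= 2 (printable ASCII starts at 32) and
the alphabet never exceeds 256 codes.  The total length is
``N = sum(n_i + 1) + 1``.

All coordinates are 0-based; intervals are half-open.  String indices in
the ``(a, b)`` pair convention are 1-based, with ``a = d + 1`` reserved
for the pseudo-string consisting of the end-marker alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

END_MARKER = 0
SEPARATOR = 1
MIN_CONTENT = 2


class ReservedByteError(ValueError):
    """An input sequence contains byte 0 or 1, which are reserved codes."""


class EmptyCollectionError(ValueError):
    """The collection holds no strings at all (d = 0)."""


@dataclass
class StringCollection:
    """An ordered list of raw input strings with identifiers.

    ``seqs`` are byte strings over printable ASCII; ``str`` inputs are
    accepted and encoded latin-1 so that bytes map one-to-one.
    """

    ids: list[str]
    seqs: list[bytes]

    def __post_init__(self) -> None:
        self.seqs = [
            s if isinstance(s, (bytes, bytearray)) else s.encode("latin-1")
            for s in self.seqs
        ]
        self.seqs = [bytes(s) for s in self.seqs]
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and seqs must have the same length")

    @classmethod
    def from_strings(cls, seqs, ids=None) -> "StringCollection":
        seqs = list(seqs)
        if ids is None:
            ids = [f"seq{i + 1}" for i in range(len(seqs))]
        return cls(ids=list(ids), seqs=seqs)

    @property
    def d(self) -> int:
        return len(self.seqs)

    @property
    def lengths(self) -> list[int]:
        return [len(s) for s in self.seqs]


@dataclass
class ConcatText:
    """The encoded concatenation ``T[0 .. N-1]``.

    ``starts`` has ``d + 1`` entries: the global start of each string,
    plus the position of the end-marker as the start of pseudo-string
    ``d + 1``.  ``sep_positions`` are the ``d`` separator positions in
    increasing order.
    """

    codes: np.ndarray
    d: int
    starts: np.ndarray
    sep_positions: np.ndarray
    ids: list[str] = field(default_factory=list)

    @property
    def N(self) -> int:
        return int(self.codes.shape[0])

    @property
    def sigma(self) -> int:
        return int(self.codes.max()) + 1

    def length_of(self, a: int) -> int:
        """Length n_a of string ``a`` (1-based); 0 for a = d + 1."""
        if not 1 <= a <= self.d + 1:
            raise IndexError(f"string index {a} out of range 1..{self.d + 1}")
        if a == self.d + 1:
            return 0
        return int(self.starts[a]) - 1 - int(self.starts[a - 1])

    def decode(self) -> list[bytes]:
        """Recover the original byte strings, in order."""
        out = []
        for a in range(1, self.d + 1):
            lo, hi = int(self.starts[a - 1]), int(self.starts[a]) - 1
            out.append(self.codes[lo:hi].astype(np.uint8).tobytes())
        return out

    def validate(self) -> None:
        codes, d, N = self.codes, self.d, self.N
        if codes[N - 1] != END_MARKER:
            raise ValueError("text must end with the end-marker (code 0)")
        sep = np.flatnonzero(codes == SEPARATOR)
        if sep.size != d or not np.array_equal(sep, self.sep_positions):
            raise ValueError("separator positions inconsistent with codes")
        if np.count_nonzero(codes == END_MARKER) != 1:
            raise ValueError("end-marker must occur exactly once")
        if self.starts.shape[0] != d + 1 or self.starts[0] != 0:
            raise ValueError("starts must have d+1 entries beginning at 0")
        expect = np.concatenate(([0], self.sep_positions + 1))
        if not np.array_equal(self.starts, expect):
            raise ValueError("starts inconsistent with separator positions")


def encode_collection(coll: StringCollection) -> ConcatText:
    """Encode a collection into its concatenated text.

    Raises :class:`EmptyCollectionError` if the collection has no
    strings and :class:`ReservedByteError` if any sequence contains a
    byte with value 0 or 1.
    """
    d = coll.d
    if d == 0:
        raise EmptyCollectionError("cannot encode a collection of 0 strings")
    N = sum(coll.lengths) + d + 1
    codes = np.empty(N, dtype=np.int64)
    starts = np.empty(d + 1, dtype=np.int64)
    sep_positions = np.empty(d, dtype=np.int64)
    pos = 0
    for i, seq in enumerate(coll.seqs):
        starts[i] = pos
        arr = np.frombuffer(seq, dtype=np.uint8)
        if arr.size and int(arr.min()) < MIN_CONTENT:
            bad = int(np.flatnonzero(arr < MIN_CONTENT)[0])
            raise ReservedByteError(
                f"string {i + 1} ({coll.ids[i]!r}) contains reserved byte "
                f"{int(arr[bad])} at offset {bad}"
            )
        codes[pos : pos + arr.size] = arr
        pos += arr.size
        sep_positions[i] = pos
        codes[pos] = SEPARATOR
        pos += 1
    starts[d] = pos
    codes[pos] = END_MARKER
    return ConcatText(
        codes=codes, d=d, starts=starts, sep_positions=sep_positions,
        ids=list(coll.ids),
    )


def concat_from_codes(codes: np.ndarray) -> ConcatText:
    """Rebuild a :class:`ConcatText` from a bare code array.

    The array must already follow the encoding convention (content
    codes >= 2, separators = 1, a single trailing end-marker = 0).
    """
    codes = np.asarray(codes, dtype=np.int64)
    sep = np.flatnonzero(codes == SEPARATOR)
    ct = ConcatText(
        codes=codes,
        d=int(sep.size),
        starts=np.concatenate(([0], sep + 1)),
        sep_positions=sep,
    )
    ct.validate()
    return ct


def global_to_local(ct: ConcatText, pos: int) -> tuple[int, int]:
    """Map a global text position to a (string index, local offset) pair.

    The separator ending string ``a`` maps to ``(a, n_a)``; the
    end-marker position ``N - 1`` maps to ``(d + 1, 0)``.
    """
    if not 0 <= pos <= ct.N - 1:
        raise IndexError(f"position {pos} out of range 0..{ct.N - 1}")
    a = int(np.searchsorted(ct.starts, pos, side="right"))
    return a, pos - int(ct.starts[a - 1])


def local_to_global(ct: ConcatText, a: int, b: int) -> int:
    """Inverse of :func:`global_to_local` on its range."""
    if not 1 <= a <= ct.d + 1:
        raise IndexError(f"string index {a} out of range 1..{ct.d + 1}")
    if not 0 <= b <= ct.length_of(a):
        raise IndexError(
            f"offset {b} out of range 0..{ct.length_of(a)} for string {a}"
        )
    return int(ct.starts[a - 1]) + b
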