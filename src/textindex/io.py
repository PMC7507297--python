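"""Reading collections and serializing index arrays.

Collections come from FASTA, FASTQ (qualities discarded) or raw text
(one string per line), optionally gzip-compressed.  Index arrays go to
disk as headerless little-endian fixed-width integers — 4 bytes by
default, 8 when values reach 2^32 — one homogeneous array per file:

====================  =============================================
``<prefix>.sa``       suffix array
``<prefix>.lcp``      LCP array
``<prefix>.da``       document array
``<prefix>.gsa.doc``  GSA string indices
``<prefix>.gsa.off``  GSA local offsets
``<prefix>.bwt``      BWT as raw rendered bytes ('#'/'$' literal)
``<prefix>.txt``      human-readable tab-separated dump
====================  =============================================

In text mode a line containing a literal ``#`` or ``$`` is rejected,
because the rendered BWT uses those characters for the markers.
"""

from __future__ import annotations

import gzip
import io as _stdio
import os
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .arrays import render_bwt
from .collection import ConcatText, StringCollection

_WIDTHS = {4: "<u4", 8: "<u8"}


class IntWidthOverflowError(OverflowError):
    """A value does not fit the chosen integer width."""


class MalformedInputError(ValueError):
    """The input file does not parse in the declared format."""


# ----------------------------------------------------------- readers


def _open_text(source, gzipped):
    if hasattr(source, "read"):
        return source, False
    path = Path(source)
    if gzipped is None:
        gzipped = path.suffix == ".gz"
    if gzipped:
        return gzip.open(path, "rt", encoding="latin-1"), True
    return open(path, "rt", encoding="latin-1"), True


def detect_format(path) -> str:
    """Guess the input format from the file extension (.gz stripped)."""
    name = Path(path).name
    if name.endswith(".gz"):
        name = name[: -len(".gz")]
    ext = Path(name).suffix.lower()
    if ext in {".fa", ".fasta", ".fna", ".faa"}:
        return "fasta"
    if ext in {".fq", ".fastq"}:
        return "fastq"
    return "text"


def read_collection(source, format: str = "text", gzipped: bool | None = None) -> StringCollection:
    """Read a string collection from a path or text stream.

    FASTA joins sequence lines per record; FASTQ keeps only the
    sequence line of each record; text mode takes one string per line
    (a final newline is optional and an empty trailing line is
    ignored).  ``gzipped=None`` autodetects from a ``.gz`` suffix.
    """
    if format == "auto":
        if hasattr(source, "read"):
            raise ValueError("format 'auto' requires a file path")
        format = detect_format(source)
    handle, close = _open_text(source, gzipped)
    try:
        if format in ("fasta", "fastq"):
            ids, seqs = [], []
            try:
                for rec in SeqIO.parse(handle, format):
                    ids.append(rec.id)
                    seqs.append(str(rec.seq).encode("latin-1"))
            except ValueError as exc:
                raise MalformedInputError(f"malformed {format} input: {exc}") from exc
            return StringCollection(ids=ids, seqs=seqs)
        if format == "text":
            ids, seqs = [], []
            lines = handle.read().split("\n")
            if lines and lines[-1] == "":
                lines.pop()
            for i, line in enumerate(lines):
                if "#" in line or "$" in line:
                    raise MalformedInputError(
                        f"text line {i + 1} contains a reserved rendering "
                        "character ('#' or '$')"
                    )
                ids.append(f"line{i + 1}")
                seqs.append(line.encode("latin-1"))
            return StringCollection(ids=ids, seqs=seqs)
        raise ValueError(f"unknown format {format!r}")
    finally:
        if close:
            handle.close()


# ------------------------------------------------- fixed-width arrays


def write_int_array(values, width: int, sink) -> int:
    """Write integers as headerless little-endian words; returns bytes
    written.  Raises :class:`IntWidthOverflowError` naming the first
    offending index if a value does not fit ``width`` bytes."""
    if width not in _WIDTHS:
        raise ValueError(f"width must be 4 or 8, got {width}")
    bound = 1 << (8 * width)
    arr = np.asarray(values)
    if arr.size == 0:
        if not hasattr(sink, "write"):
            Path(sink).write_bytes(b"")
        return 0
    if arr.dtype == object or not np.issubdtype(arr.dtype, np.integer):
        vals = [int(v) for v in np.ravel(arr)]
        for i, v in enumerate(vals):
            if not 0 <= v < bound:
                raise IntWidthOverflowError(
                    f"value {v} at index {i} does not fit in {width} bytes"
                )
        arr = np.array(vals, dtype=np.uint64)
    else:
        lo = int(arr.min())
        hi = int(arr.max())
        if lo < 0 or hi >= bound:
            mask = (arr < 0) | (arr.astype(np.uint64) >= np.uint64(bound))
            i = int(np.flatnonzero(mask)[0])
            raise IntWidthOverflowError(
                f"value {int(arr[i])} at index {i} does not fit in {width} bytes"
            )
    out = arr.astype(_WIDTHS[width])
    if hasattr(sink, "write"):
        data = out.tobytes()
        sink.write(data)
        return len(data)
    out.tofile(sink)
    return out.size * width


def read_int_array(source, width: int) -> np.ndarray:
    """Exact inverse of :func:`write_int_array`."""
    if width not in _WIDTHS:
        raise ValueError(f"width must be 4 or 8, got {width}")
    size = os.path.getsize(source)
    if size % width:
        raise MalformedInputError(
            f"file size {size} is not a multiple of width {width}"
        )
    return np.fromfile(source, dtype=_WIDTHS[width])


# ------------------------------------------------------------- dumps


def render_text(codes: np.ndarray) -> str:
    """Render a code slice with literal '#' and '$' markers."""
    return render_bwt(codes).decode("latin-1")


def write_txt_dump(
    ct: ConcatText,
    sink,
    sa: np.ndarray,
    lcp: np.ndarray | None = None,
    da: np.ndarray | None = None,
    bwt: np.ndarray | None = None,
    max_suffix_chars: int = 40,
) -> None:
    """Human-readable dump: one row per suffix with the requested
    columns (i, SA, DA, LCP, BWT) and the truncated suffix itself."""
    cols = ["i", "SA"]
    if da is not None:
        cols.append("DA")
    if lcp is not None:
        cols.append("LCP")
    if bwt is not None:
        cols.append("BWT")
    cols.append("suffix")
    own = not hasattr(sink, "write")
    handle = open(sink, "w", encoding="latin-1") if own else sink
    try:
        handle.write("\t".join(cols) + "\n")
        for i in range(ct.N):
            p = int(sa[i])
            row = [str(i), str(p)]
            if da is not None:
                row.append(str(int(da[i])))
            if lcp is not None:
                row.append(str(int(lcp[i])))
            if bwt is not None:
                row.append(render_text(np.asarray(bwt[i : i + 1])))
            row.append(render_text(ct.codes[p : p + max_suffix_chars]))
            handle.write("\t".join(row) + "\n")
    finally:
        if own:
            handle.close()


def write_fixture(
    coll: StringCollection, path, format: str = "fasta", gzipped: bool = False
) -> None:
    """Write a collection back out as a FASTA/FASTQ/text fixture file."""
    buf = _stdio.StringIO()
    if format == "fasta":
        for name, seq in zip(coll.ids, coll.seqs):
            buf.write(f">{name}\n{seq.decode('latin-1')}\n")
    elif format == "fastq":
        for name, seq in zip(coll.ids, coll.seqs):
            s = seq.decode("latin-1")
            buf.write(f"@{name}\n{s}\n+\n{'I' * len(s)}\n")
    elif format == "text":
        for seq in coll.seqs:
            buf.write(seq.decode("latin-1") + "\n")
    else:
        raise ValueError(f"unknown fixture format {format!r}")
    data = buf.getvalue().encode("latin-1")
    if gzipped:
        with gzip.open(path, "wb") as fh:
            fh.write(data)
    else:
        Path(path).write_bytes(data)
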