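"""Paired FASTQ input/output, transparently gzip-aware."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterator, Sequence

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ..errors import FormatError


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if "r" in mode:
        with open(path, "rb") as probe:
            magic = probe.read(2)
        if magic == b"\x1f\x8b":
            return gzip.open(path, mode)
        return open(path, mode)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _records(path: str | Path) -> Iterator[tuple[str, str]]:
    with _open_text(path) as handle:
        try:
            for title, seq, _qual in FastqGeneralIterator(handle):
                yield title.split()[0], seq.upper()
        except ValueError as exc:  # truncated / malformed record
            raise FormatError(f"{path}: {exc}") from exc


def read_fastq_pairs(
    paths: Sequence[str | Path], interleaved: bool = False
) -> Iterator[tuple[str, str, str]]:
    """Yield ``(pair_id, r1_seq, r2_seq)`` in file order.

    ``paths`` is either ``[r1, r2]`` (or both given, non-interleaved) or a
    single interleaved file.  A stream-length mismatch raises a
    :class:`FormatError` naming the offending record number.
    """
    if interleaved:
        if len(paths) != 1:
            raise FormatError("interleaved input takes exactly one FASTQ file")
        it = _records(paths[0])
        n = 0
        while True:
            first = next(it, None)
            if first is None:
                return
            n += 1
            second = next(it, None)
            if second is None:
                raise FormatError(
                    f"{paths[0]}: interleaved pair {n} is missing its mate"
                )
            yield first[0], first[1], second[1]
    else:
        if len(paths) != 2:
            raise FormatError("paired input takes exactly two FASTQ files (R1, R2)")
        it1, it2 = _records(paths[0]), _records(paths[1])
        n = 0
        while True:
            a = next(it1, None)
            b = next(it2, None)
            n += 1
            if a is None and b is None:
                return
            if a is None or b is None:
                longer = paths[1] if a is None else paths[0]
                raise FormatError(
                    f"R1/R2 length mismatch: {longer} has an unmatched record {n}"
                )
            yield a[0], a[1], b[1]


def write_fastq_pair_files(
    r1_seqs: Sequence[str],
    r2_seqs: Sequence[str],
    r1_path: str | Path,
    r2_path: str | Path,
    id_prefix: str = "p",
) -> None:
    """Write mate sequences to R1/R2 FASTQ files (constant quality)."""
    if len(r1_seqs) != len(r2_seqs):
        raise FormatError("R1/R2 sequence lists differ in length")
    for mate, path, seqs in ((1, r1_path, r1_seqs), (2, r2_path, r2_seqs)):
        with _open_text(path, "wt") as out:
            for i, seq in enumerate(seqs):
                out.write(f"@{id_prefix}{i}/{mate}\n{seq}\n+\n{'I' * len(seq)}\n")
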