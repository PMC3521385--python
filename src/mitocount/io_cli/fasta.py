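"""FASTA helpers for the reference and consensus sequences."""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO

from ..errors import FormatError
from ..mito_typing import ReferenceMito
from .fastq import _open_text


def read_single_fasta(path: str | Path) -> ReferenceMito:
    """Load exactly one record; multi-record input is an error naming the count."""
    with _open_text(path) as handle:
        records = list(SeqIO.parse(handle, "fasta"))
    if len(records) != 1:
        raise FormatError(
            f"{path}: expected a single FASTA record, found {len(records)}"
        )
    rec = records[0]
    return ReferenceMito(id=rec.id, sequence=str(rec.seq).upper())


def write_fasta(seq_id: str, sequence: str, path: str | Path, width: int = 70) -> None:
    with _open_text(path, "wt") as out:
        out.write(f">{seq_id}\n")
        for i in range(0, len(sequence), width):
            out.write(sequence[i : i + width] + "\n")
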