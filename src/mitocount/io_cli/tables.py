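"""Frozen CSV schemas for per-run counts and per-sample summaries."""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence

from ..copy_number import CopyNumberEstimate
from ..errors import FormatError
from ..read_classifier import RunCount

RUN_CSV_HEADER = ["run_id", "total_reads", "mito_reads", "all_bases", "mt_bases", "mt_ratio"]
SUMMARY_CSV_HEADER = ["sample", "runs", "all_bases", "mt_bases", "mt_ratio", "k"]


def write_run_csv(counts: Sequence[RunCount], path: str | Path) -> None:
    """One row per run; integers unformatted, ratio to 6 significant digits."""
    if not counts:
        raise FormatError("write_run_csv: refusing to write an empty run table")
    with open(path, "w", newline="") as out:
        writer = csv.writer(out)
        writer.writerow(RUN_CSV_HEADER)
        for c in counts:
            ratio = c.mt_bases / c.all_bases if c.all_bases else 0.0
            writer.writerow(
                [c.run_id, c.total_reads, c.mito_reads, c.all_bases, c.mt_bases, f"{ratio:.6g}"]
            )


def read_run_csv(path: str | Path) -> list[RunCount]:
    with open(path, newline="") as handle:
        reader = csv.reader(handle)
        header = next(reader, None)
        if header != RUN_CSV_HEADER:
            raise FormatError(f"{path}: unexpected run CSV header {header}")
        counts = []
        for i, row in enumerate(reader, start=2):
            if len(row) != len(RUN_CSV_HEADER):
                raise FormatError(f"{path}: malformed row at line {i}")
            counts.append(
                RunCount(
                    run_id=row[0],
                    total_reads=int(row[1]),
                    mito_reads=int(row[2]),
                    all_bases=int(row[3]),
                    mt_bases=int(row[4]),
                )
            )
    return counts


def write_summary_csv(
    sample_id: str, n_runs: int, estimate: CopyNumberEstimate, path: str | Path
) -> None:
    with open(path, "w", newline="") as out:
        writer = csv.writer(out)
        writer.writerow(SUMMARY_CSV_HEADER)
        writer.writerow(
            [
                sample_id,
                n_runs,
                estimate.pooled_all_bases,
                estimate.pooled_mt_bases,
                f"{estimate.pooled_ratio:.6g}",
                f"{estimate.k:.6g}",
            ]
        )
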