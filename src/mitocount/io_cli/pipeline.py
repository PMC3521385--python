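"""The three-stage driver: type the consensus, count runs, estimate copies."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from ..copy_number import CopyNumberEstimate, GenomeParams, aggregate_runs
from ..errors import FormatError, MitoCountError
from ..mito_typing import MitoConsensus, ReferenceMito, TypingParams, type_consensus
from ..read_classifier import PairingParams, RunCount, build_index, count_run
from .fasta import read_single_fasta, write_fasta
from .fastq import read_fastq_pairs
from .tables import write_run_csv, write_summary_csv

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunSpec:
    run_id: str
    paths: tuple[str, ...]
    interleaved: bool = False


@dataclass(frozen=True)
class RunManifest:
    """A sample and its sequencing runs (the unit the per-run CSV reports)."""

    sample_id: str
    runs: tuple[RunSpec, ...]

    def __post_init__(self) -> None:
        ids = [r.run_id for r in self.runs]
        if len(set(ids)) != len(ids):
            raise FormatError(f"duplicate run_id in manifest for {self.sample_id!r}")
        for run in self.runs:
            for p in run.paths:
                if not Path(p).exists():
                    raise FormatError(f"manifest file not found: {p}")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunManifest":
        with open(path) as handle:
            data = json.load(handle)
        runs = tuple(
            RunSpec(
                run_id=r["run_id"],
                paths=tuple(r["paths"]),
                interleaved=bool(r.get("interleaved", False)),
            )
            for r in data.get("runs", [])
        )
        return cls(sample_id=data["sample_id"], runs=runs)


@dataclass(frozen=True)
class SampleSummary:
    sample_id: str
    consensus: MitoConsensus
    run_counts: tuple[RunCount, ...]
    estimate: CopyNumberEstimate


def _stage(name: str):
    """Decorator-free helper: re-raise stage errors with the stage name."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, MitoCountError):
                exc.args = (f"[{name}] {exc}",)
            return False

    return _Ctx()


def run_pipeline(
    manifest: RunManifest,
    reference_path: str | Path,
    nuclear_bases: int,
    out_dir: str | Path,
    typing_params: TypingParams = TypingParams(),
    pairing_params: PairingParams = PairingParams(),
    ploidy_factor: int = 2,
    max_typing_reads: Optional[int] = 12000,
) -> SampleSummary:
    """Execute typing -> per-run counting -> copy-number estimation.

    Writes ``<sample>.consensus.fasta``, ``<sample>.consensus.txt``,
    ``<sample>.runs.csv`` and ``<sample>.summary.csv`` under ``out_dir``.
    Output files contain no timestamps, so reruns are byte-identical.
    """
    if not manifest.runs:
        raise FormatError(f"manifest for {manifest.sample_id!r} lists no runs")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    reference = read_single_fasta(reference_path)

    def all_reads():
        for run in manifest.runs:
            for _pid, r1, r2 in read_fastq_pairs(run.paths, run.interleaved):
                yield r1
                yield r2

    with _stage("type"):
        logger.info("stage type: assembling consensus for %s", manifest.sample_id)
        consensus = type_consensus(
            all_reads(), reference, typing_params, max_typing_reads=max_typing_reads
        )
    prefix = out_dir / manifest.sample_id
    write_fasta(manifest.sample_id, consensus.sequence, f"{prefix}.consensus.fasta")
    _write_consensus_report(consensus, reference, f"{prefix}.consensus.txt")

    with _stage("count"):
        index = build_index(consensus, pairing_params.seed_length)
        counts = []
        for run in manifest.runs:
            logger.info("stage count: run %s", run.run_id)
            pairs = (
                (r1, r2) for _pid, r1, r2 in read_fastq_pairs(run.paths, run.interleaved)
            )
            counts.append(count_run(pairs, index, pairing_params, run.run_id))
    write_run_csv(counts, f"{prefix}.runs.csv")

    with _stage("estimate"):
        params = GenomeParams(
            N=nuclear_bases, M=consensus.length_bp, ploidy_factor=ploidy_factor
        )
        estimate = aggregate_runs(counts, params)
    write_summary_csv(manifest.sample_id, len(counts), estimate, f"{prefix}.summary.csv")
    logger.info(
        "sample %s: k = %.2f over %d run(s)", manifest.sample_id, estimate.k, len(counts)
    )
    return SampleSummary(
        sample_id=manifest.sample_id,
        consensus=consensus,
        run_counts=tuple(counts),
        estimate=estimate,
    )


def _write_consensus_report(
    consensus: MitoConsensus, reference: ReferenceMito, path: str | Path
) -> None:
    lines = [
        f"length_bp\t{consensus.length_bp}",
        f"reference_length_bp\t{len(reference)}",
        f"mean_support\t{consensus.mean_support():.3f}",
    ]
    if consensus.length_bp == len(reference):
        mismatches = sum(
            1 for a, b in zip(consensus.sequence, reference.sequence) if a != b
        )
        lines.append(f"reference_mismatches\t{mismatches}")
    else:
        lines.append("reference_mismatches\tNA (length differs)")
    Path(path).write_text("\n".join(lines) + "\n")
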