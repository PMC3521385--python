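"""Copy-number arithmetic and group-comparison statistics.

A WGS run samples nuclear and mitochondrial molecules in proportion to
their base content, so for a diploid nuclear genome of ``ploidy * N``
bases and a mitochondrial genome of ``M`` bases present in ``k`` copies:

    mtBases / allBases = k*M / (ploidy*N + k*M)

which inverts to the estimator

    k = mtBases * ploidy * N / ((allBases - mtBases) * M)

Group comparisons use a classical one-way fixed-effects ANOVA over per-run
mitochondrial base ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, ParameterError
from .read_classifier import RunCount


@dataclass(frozen=True)
class GenomeParams:
    """Genome size constants consumed by the copy-number estimator."""

    N: int  # haploid nuclear base count (bp)
    M: int  # mitochondrial genome length (bp)
    ploidy_factor: int = 2

    def __post_init__(self) -> None:
        if self.N <= 0:
            raise ParameterError(f"N must be positive, got {self.N}")
        if self.M <= 0:
            raise ParameterError(f"M must be positive, got {self.M}")
        if self.ploidy_factor < 1:
            raise ParameterError(f"ploidy_factor must be >= 1, got {self.ploidy_factor}")


@dataclass(frozen=True)
class CopyNumberEstimate:
    k: float
    per_run_ratios: tuple[float, ...]
    pooled_mt_bases: int
    pooled_all_bases: int
    genome_params: GenomeParams

    @property
    def k_rounded(self) -> float:
        return round(self.k, 2)

    @property
    def pooled_ratio(self) -> float:
        return self.pooled_mt_bases / self.pooled_all_bases


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p_value: float
    group_means: tuple[float, ...]


def mito_ratio(run: RunCount) -> float:
    """Fraction of sequenced bases that came from mitochondrial pairs."""
    if run.all_bases <= 0:
        raise DegenerateInputError(
            f"run {run.run_id!r}: ratio undefined with all_bases = {run.all_bases}"
        )
    return run.mt_bases / run.all_bases


def estimate_copies(mt_bases: float, all_bases: float, params: GenomeParams) -> float:
    """Estimated mtDNA copies per nuclear genome equivalent."""
    if mt_bases < 0 or all_bases <= mt_bases:
        raise DegenerateInputError(
            f"need all_bases > mt_bases >= 0, got mt_bases={mt_bases}, "
            f"all_bases={all_bases}"
        )
    return (mt_bases * params.ploidy_factor * params.N) / (
        (all_bases - mt_bases) * params.M
    )


def copies_from_ratio(ratio: float, params: GenomeParams) -> float:
    """Copy number implied by a mitochondrial base ratio (same estimator)."""
    if not (0 <= ratio < 1):
        raise DegenerateInputError(f"ratio must be in [0, 1), got {ratio}")
    return ratio * params.ploidy_factor * params.N / ((1 - ratio) * params.M)


def implied_diploid_bases(k: float, mt_bases: float, all_bases: float, m: int) -> float:
    """Invert the estimator for the diploid nuclear base count ``ploidy*N``.

    Useful for cross-checking published (k, mtBases, allBases) triples that
    omit the nuclear genome size they were computed with.
    """
    if mt_bases <= 0:
        raise DegenerateInputError("mt_bases must be positive to invert")
    return k * (all_bases - mt_bases) * m / mt_bases


def aggregate_runs(runs: Sequence[RunCount], params: GenomeParams) -> CopyNumberEstimate:
    """Pool counts across runs and estimate k from the pooled sums."""
    if not runs:
        raise DegenerateInputError("aggregate_runs: empty run list")
    ratios = tuple(mito_ratio(r) for r in runs)
    mt = sum(r.mt_bases for r in runs)
    total = sum(r.all_bases for r in runs)
    return CopyNumberEstimate(
        k=estimate_copies(mt, total, params),
        per_run_ratios=ratios,
        pooled_mt_bases=mt,
        pooled_all_bases=total,
        genome_params=params,
    )


def oneway_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """One-way fixed-effects ANOVA over per-run values.

    Degenerate case: zero within-group variance with unequal means yields
    an infinite F and p = 0; identical values everywhere yield F = 0.
    """
    if len(groups) < 2:
        raise DegenerateInputError("ANOVA needs at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for i, g in enumerate(arrays):
        if g.size < 2:
            raise DegenerateInputError(f"ANOVA group {i} has fewer than 2 observations")
    n_total = sum(g.size for g in arrays)
    n_groups = len(arrays)
    df_between = n_groups - 1
    df_within = n_total - n_groups
    grand_mean = sum(g.sum() for g in arrays) / n_total
    means = tuple(float(g.mean()) for g in arrays)
    ss_between = sum(g.size * (mu - grand_mean) ** 2 for g, mu in zip(arrays, means))
    ss_within = sum(float(((g - mu) ** 2).sum()) for g, mu in zip(arrays, means))
    if ss_within == 0.0:
        if ss_between <= 1e-30:
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = math.inf, 0.0
    else:
        f_stat = (ss_between / df_between) / (ss_within / df_within)
        p = float(stats.f.sf(f_stat, df_between, df_within))
    return AnovaResult(
        F=float(f_stat),
        df_between=df_between,
        df_within=df_within,
        p_value=p,
        group_means=means,
    )
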