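"""Synthetic paired-end WGS generator with a planted mtDNA copy number.

Each read pair originates from the mitochondrial circle with probability
``k*M / (ploidy*N + k*M)`` and from the linear nuclear sequence otherwise,
mirroring the premise that a shotgun run samples molecules in proportion
to their base content.  Fragments start uniformly on the chosen molecule
(wrapping on the circle), mates read inward from the fragment ends, and
i.i.d. substitution errors are applied per base.  Truth labels, the true
(possibly reference-divergent) mitochondrial haplotype and all planted
variant positions are returned alongside the reads.

All randomness flows from ``SimSpec.seed`` through one generator, so a
spec reproduces its dataset byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import _dna
from .errors import ParameterError

MITO = "mito"
NUCLEAR = "nuclear"

_CHUNK = 20000  # pairs generated per vectorized block


@dataclass(frozen=True)
class SimSpec:
    """Full parameterization of one synthetic dataset."""

    nuclear_length: int  # haploid nuclear base count N (diploid total = ploidy*N)
    mito_length: int
    true_k: float
    read_length: int = 100
    n_pairs: int = 10000
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    error_rate: float = 0.0
    mito_divergence: int = 0
    heteroplasmy_fraction: float = 0.0
    heteroplasmy_sites: int = 1
    numt_length: int = 0  # optional planted nuclear copy of a mito segment
    ploidy_factor: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nuclear_length <= 0 or self.mito_length <= 0 or self.read_length <= 0:
            raise ParameterError("all lengths must be positive")
        if self.true_k <= 0:
            raise ParameterError("true_k must be positive")
        if not (0 <= self.error_rate < 0.5):
            raise ParameterError("error_rate must be in [0, 0.5)")
        if not (0 <= self.heteroplasmy_fraction < 0.5):
            raise ParameterError("heteroplasmy_fraction must be in [0, 0.5)")
        if self.mito_divergence > self.mito_length:
            raise ParameterError("mito_divergence exceeds mito_length")
        if self.numt_length > min(self.mito_length, self.nuclear_length):
            raise ParameterError("numt_length exceeds a genome length")
        if self.insert_mean < self.read_length:
            raise ParameterError("insert_mean must be >= read_length")

    @property
    def mito_pair_probability(self) -> float:
        km = self.true_k * self.mito_length
        return km / (self.ploidy_factor * self.nuclear_length + km)


@dataclass(frozen=True)
class GenomeTriple:
    nuclear: str
    mito_true: str
    mito_reference: str
    divergence_positions: tuple[int, ...]


@dataclass
class TruthSet:
    """Per-pair origin labels plus the planted ground truth."""

    labels: np.ndarray  # bool, True = mitochondrial
    mito_true: str
    divergence_positions: tuple[int, ...]
    heteroplasmy_positions: tuple[int, ...]
    minor_haplotype: Optional[str] = None

    @property
    def n_pairs(self) -> int:
        return int(self.labels.size)

    @property
    def mito_pair_count(self) -> int:
        return int(self.labels.sum())


@dataclass
class SimReads:
    r1: list[str]
    r2: list[str]
    truth: TruthSet


def _random_codes(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n, dtype=np.uint8)


def _substitute(
    rng: np.random.Generator, codes: np.ndarray, positions: np.ndarray
) -> np.ndarray:
    """Replace each listed position with a different uniformly chosen base."""
    out = codes.copy()
    shift = rng.integers(1, 4, size=positions.size, dtype=np.uint8)
    out[positions] = (out[positions] + shift) % 4
    return out


def simulate_genome(spec: SimSpec) -> GenomeTriple:
    """Draw the nuclear sequence, reference mito and true (divergent) mito."""
    rng = np.random.default_rng(spec.seed)
    nuclear = _random_codes(rng, spec.nuclear_length)
    mito_ref = _random_codes(rng, spec.mito_length)
    div_pos = np.sort(
        rng.choice(spec.mito_length, size=spec.mito_divergence, replace=False)
    )
    mito_true = _substitute(rng, mito_ref, div_pos)
    if spec.numt_length > 0:
        at = int(rng.integers(0, spec.nuclear_length - spec.numt_length + 1))
        nuclear[at : at + spec.numt_length] = mito_ref[: spec.numt_length]
    return GenomeTriple(
        nuclear=_dna.decode(nuclear),
        mito_true=_dna.decode(mito_true),
        mito_reference=_dna.decode(mito_ref),
        divergence_positions=tuple(int(p) for p in div_pos),
    )


def _read_windows(
    genome: np.ndarray, starts: np.ndarray, length: int, circular: bool
) -> np.ndarray:
    offs = np.arange(length)
    pos = starts[:, None] + offs[None, :]
    if circular:
        pos %= genome.shape[0]
    return genome[pos]


def _apply_errors(rng: np.random.Generator, reads: np.ndarray, rate: float) -> np.ndarray:
    if rate <= 0:
        return reads
    mask = rng.random(reads.shape) < rate
    shift = rng.integers(1, 4, size=reads.shape, dtype=np.uint8)
    return np.where(mask, (reads + shift) % 4, reads)


def simulate_reads(spec: SimSpec, genome: GenomeTriple) -> SimReads:
    """Generate the paired reads and truth labels for a genome triple.

    The fragment strand is randomized per pair (mates are swapped with
    probability 1/2) so both orientations occur in R1.
    """
    rng = np.random.default_rng(spec.seed + 1)
    nuclear = _dna.encode(genome.nuclear)
    mito_true = _dna.encode(genome.mito_true)
    m = spec.mito_length
    n_len = spec.nuclear_length
    rl = spec.read_length

    het_pos: tuple[int, ...] = ()
    minor: Optional[np.ndarray] = None
    if spec.heteroplasmy_fraction > 0:
        het = np.sort(rng.choice(m, size=spec.heteroplasmy_sites, replace=False))
        minor = _substitute(rng, mito_true, het)
        het_pos = tuple(int(p) for p in het)

    labels = rng.random(spec.n_pairs) < spec.mito_pair_probability
    insert_hi = 4.0 * spec.insert_mean
    r1_out: list[str] = ["" for _ in range(spec.n_pairs)]
    r2_out: list[str] = ["" for _ in range(spec.n_pairs)]

    for lo in range(0, spec.n_pairs, _CHUNK):
        hi = min(lo + _CHUNK, spec.n_pairs)
        nblk = hi - lo
        blk_labels = labels[lo:hi]
        inserts = np.clip(
            np.rint(rng.normal(spec.insert_mean, spec.insert_sd, size=nblk)),
            rl,
            insert_hi,
        ).astype(np.int64)
        if np.any(inserts[~blk_labels] > n_len):
            raise ParameterError("insert longer than the nuclear molecule")
        starts = np.empty(nblk, dtype=np.int64)
        is_mito = blk_labels
        starts[is_mito] = rng.integers(0, m, size=int(is_mito.sum()))
        nuc_n = int((~is_mito).sum())
        # uniform over valid linear starts for each nuclear insert length
        u = rng.random(nuc_n)
        max_start = n_len - inserts[~is_mito]
        starts[~is_mito] = np.floor(u * (max_start + 1)).astype(np.int64)

        left = np.empty((nblk, rl), dtype=np.uint8)
        right = np.empty((nblk, rl), dtype=np.uint8)
        if nuc_n:
            ns = starts[~is_mito]
            ni = inserts[~is_mito]
            left[~is_mito] = _read_windows(nuclear, ns, rl, circular=False)
            right[~is_mito] = _read_windows(nuclear, ns + ni - rl, rl, circular=False)
        mito_n = int(is_mito.sum())
        if mito_n:
            ms = starts[is_mito]
            mi = inserts[is_mito]
            if minor is not None:
                from_minor = rng.random(mito_n) < spec.heteroplasmy_fraction
                lmaj = _read_windows(mito_true, ms, rl, circular=True)
                rmaj = _read_windows(mito_true, ms + mi - rl, rl, circular=True)
                lmin = _read_windows(minor, ms, rl, circular=True)
                rmin = _read_windows(minor, ms + mi - rl, rl, circular=True)
                left[is_mito] = np.where(from_minor[:, None], lmin, lmaj)
                right[is_mito] = np.where(from_minor[:, None], rmin, rmaj)
            else:
                left[is_mito] = _read_windows(mito_true, ms, rl, circular=True)
                right[is_mito] = _read_windows(mito_true, ms + mi - rl, rl, circular=True)

        r1 = left
        r2 = _dna._COMP_CODE[right[:, ::-1]]  # inward-facing mate
        r1 = _apply_errors(rng, r1, spec.error_rate)
        r2 = _apply_errors(rng, r2, spec.error_rate)
        swap = rng.random(nblk) < 0.5
        for j in range(nblk):
            a = _dna.decode(r1[j])
            b = _dna.decode(r2[j])
            if swap[j]:
                a, b = b, a
            r1_out[lo + j] = a
            r2_out[lo + j] = b

    truth = TruthSet(
        labels=labels,
        mito_true=genome.mito_true,
        divergence_positions=genome.divergence_positions,
        heteroplasmy_positions=het_pos,
        minor_haplotype=None if minor is None else _dna.decode(minor),
    )
    return SimReads(r1=r1_out, r2=r2_out, truth=truth)


def simulate_dataset(spec: SimSpec) -> tuple[GenomeTriple, SimReads]:
    """Genome + reads in one call."""
    genome = simulate_genome(spec)
    return genome, simulate_reads(spec, genome)
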