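"""Guided typing of the sample's homoplasmic mitochondrial consensus.

Given a reference mitochondrial genome and a pool of WGS reads, this module
picks a beginning read anchored near the reference origin and an ending
read anchored near the reference end, then greedily extends the beginning
read rightward — at each step the unused read with the longest verified
suffix/prefix overlap wins — until the ending read is incorporated.  The
per-position consensus base is the majority vote of every read covering
that position, so the result follows the sample (including homoplasmic
differences from the guide reference), not the reference.

Coordinates are 0-based half-open; the consensus is reported linearized at
the reference origin, with the junction between the ending and beginning
anchors closing the circle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from . import _dna
from .errors import (
    AssemblyGapError,
    ConsensusError,
    InsufficientCoverageError,
    ParameterError,
    RunawayAssemblyError,
)
from .read_classifier import FORWARD, MitoIndex, map_read

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReferenceMito:
    """A circular reference mitochondrial genome."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ParameterError("reference mtDNA sequence is empty")
        _dna.validate_alphabet(self.sequence, what=f"reference {self.id!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AnchorRead:
    sequence: str  # oriented to the reference forward strand
    read_index: int  # position of the source read in the input stream
    offset: int  # 0-based anchor position on the reference
    mismatches: int


@dataclass(frozen=True)
class AnchorReads:
    beginning: AnchorRead
    ending: AnchorRead

    # convenience aliases mirroring the domain vocabulary
    @property
    def begin_offset(self) -> int:
        return self.beginning.offset

    @property
    def end_offset(self) -> int:
        return self.ending.offset


@dataclass
class MitoConsensus:
    """The typed homoplasmic circular mtDNA sequence of one sample."""

    sequence: str
    per_base_support: np.ndarray

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.per_base_support):
            raise ConsensusError("consensus sequence and support lengths differ")
        if len(self.sequence) == 0:
            raise ConsensusError("empty consensus")
        if np.any(self.per_base_support < 1):
            raise ConsensusError("consensus has unsupported positions")

    @property
    def length_bp(self) -> int:
        return len(self.sequence)

    def mean_support(self) -> float:
        return float(np.mean(self.per_base_support))


@dataclass(frozen=True)
class TypingParams:
    """Tunables for anchor selection and greedy extension."""

    min_overlap: int = 31
    max_overlap_mismatch_rate: float = 0.05
    max_length: Optional[int] = None  # None -> reference length + 2000
    anchor_window: int = 200
    max_anchor_mismatch_rate: float = 0.10
    length_tolerance: int = 500
    index_seed_length: int = 12
    index_stride: int = 4  # read offsets sampled into the overlap seed table
    # contig tail positions probed per extension step; must be long enough
    # that a sequencing error in the low-coverage growing edge still leaves
    # a clean, well-covered seed inside the probe window
    tail_backoff: int = 64

    def __post_init__(self) -> None:
        if self.min_overlap < self.index_seed_length:
            raise ParameterError("min_overlap must be >= index_seed_length")
        if not (0 <= self.max_overlap_mismatch_rate < 1):
            raise ParameterError("max_overlap_mismatch_rate must be in [0, 1)")


def screen_reads(
    reads: Iterable[str],
    reference: ReferenceMito,
    max_reads: Optional[int] = None,
    seed_length: int = 16,
    stride: int = 8,
) -> list[str]:
    """Cheap reference-guided prefilter of a bulk WGS stream.

    Keeps reads sharing at least one exact ``seed_length``-mer with the
    circular reference on either strand, in input order, stopping once
    ``max_reads`` are collected.  This bounds the cost of typing on deep
    datasets without touching the consensus itself (candidate reads are
    still placed and voted individually).
    """
    m = len(reference)
    ref_doubled = (reference.sequence * 2).encode("ascii")
    seeds = {ref_doubled[p : p + seed_length] for p in range(m)}
    kept: list[str] = []
    for read in reads:
        hit = False
        for seq in (read, _dna.revcomp(read)):
            b = seq.encode("ascii")
            last = len(b) - seed_length
            if last < 0:
                continue
            offsets = list(range(0, last + 1, stride))
            if offsets and offsets[-1] != last:
                offsets.append(last)
            if any(b[o : o + seed_length] in seeds for o in offsets):
                hit = True
                break
        if hit:
            kept.append(read)
            if max_reads is not None and len(kept) >= max_reads:
                break
    return kept


def select_anchor_reads(
    reads: Sequence[str],
    reference: ReferenceMito,
    params: TypingParams = TypingParams(),
) -> AnchorReads:
    """Choose the beginning and ending anchor reads from the pool.

    The beginning read is the one placing best (fewest mismatches, ties by
    input order) with its start inside the reference start window; the
    ending read the one whose end falls inside the reference end window.
    Wrap-around placements are excluded so both anchors sit on the
    linearized reference.
    """
    reads = list(reads)
    if not reads:
        raise InsufficientCoverageError("beginning", "empty read pool")
    m = len(reference)
    window = min(params.anchor_window, m)
    index = MitoIndex(reference.sequence, params.index_seed_length)
    best_begin: Optional[AnchorRead] = None
    best_end: Optional[AnchorRead] = None
    for i, read in enumerate(reads):
        max_mm = int(params.max_anchor_mismatch_rate * len(read))
        for placement in map_read(read, index, max_mm, stride=params.index_stride):
            oriented = read if placement.strand == FORWARD else _dna.revcomp(read)
            end = placement.position + len(read)
            if placement.position < window and end <= m:
                cand = AnchorRead(oriented, i, placement.position, placement.mismatches)
                if best_begin is None or placement.mismatches < best_begin.mismatches:
                    best_begin = cand
            if end > m - window and end <= m:
                cand = AnchorRead(oriented, i, placement.position, placement.mismatches)
                if best_end is None or placement.mismatches < best_end.mismatches:
                    best_end = cand
    if best_begin is None:
        raise InsufficientCoverageError("beginning")
    if best_end is None:
        raise InsufficientCoverageError("ending")
    return AnchorReads(beginning=best_begin, ending=best_end)


class _Contig:
    """Growable pileup of placed reads with a lazily updated majority row."""

    def __init__(self, capacity: int):
        self.counts = np.zeros((4, capacity), dtype=np.int32)
        self.seq = np.full(capacity, _dna.N, dtype=np.uint8)
        self.length = 0

    def _ensure(self, end: int) -> None:
        cap = self.counts.shape[1]
        if end > cap:
            grow = max(end - cap, cap // 2)
            self.counts = np.pad(self.counts, ((0, 0), (0, grow)))
            self.seq = np.pad(self.seq, (0, grow), constant_values=_dna.N)

    def add(self, codes: np.ndarray, start: int) -> None:
        end = start + codes.shape[0]
        self._ensure(end)
        for base in range(4):
            mask = codes == base
            if mask.any():
                self.counts[base, start:end][mask] += 1
        block = self.counts[:, start:end]
        maj = np.argmax(block, axis=0).astype(np.uint8)
        maj[block.sum(axis=0) == 0] = _dna.N  # all-N columns stay undetermined
        self.seq[start:end] = maj
        if end > self.length:
            self.length = end


def _place_on_tail(
    contig: _Contig, codes: np.ndarray, max_back: int, mismatch_rate: float
) -> Optional[tuple[int, int]]:
    """Exhaustively align a read against the recent contig tail.

    Fallback used to locate the ending read when seed lookups miss it.
    Returns (start, mismatches) of the best full containment, or None.
    """
    n = codes.shape[0]
    lo = max(0, contig.length - max_back - n)
    best: Optional[tuple[int, int]] = None
    for start in range(lo, contig.length - n + 1):
        mm = _dna.hamming(codes, contig.seq[start : start + n])
        if mm <= int(mismatch_rate * n) and (best is None or mm < best[1]):
            best = (start, mm)
    return best


def assemble_consensus(
    reads: Sequence[str],
    anchors: AnchorReads,
    reference: ReferenceMito,
    params: TypingParams = TypingParams(),
) -> MitoConsensus:
    """Greedy guided overlap assembly from the beginning to the ending read.

    Deterministic for a fixed read order: candidate ranking is (longest
    overlap, fewest overlap mismatches, input order).  Reads that fall
    entirely inside the contig are absorbed into the pileup when
    encountered so every position gets full majority-vote support.  After
    the ending read is met, extension continues one read length past it so
    the origin junction is covered, the circle period is detected, and
    wrapped columns are folded back onto the start.
    """
    reads = list(reads)
    s = params.index_seed_length
    max_length = params.max_length or len(reference) + 2000
    # oriented pool: even ids forward, odd ids reverse-complement
    oriented: list[bytes] = []
    for read in reads:
        oriented.append(read.encode("ascii"))
        oriented.append(_dna.revcomp(read).encode("ascii"))

    table: dict[bytes, list[tuple[int, int]]] = {}
    for oidx, b in enumerate(oriented):
        last = len(b) - s
        for off in range(0, last + 1, params.index_stride):
            table.setdefault(b[off : off + s], []).append((oidx, off))

    used = [False] * len(reads)
    codes_cache: dict[int, np.ndarray] = {}

    def ocodes(oidx: int) -> np.ndarray:
        arr = codes_cache.get(oidx)
        if arr is None:
            arr = _dna.encode(oriented[oidx])
            codes_cache[oidx] = arr
        return arr

    contig = _Contig(capacity=max_length + 200)
    begin = anchors.beginning
    end_read = anchors.ending
    contig.add(_dna.encode(begin.sequence), 0)
    used[begin.read_index] = True
    end_contig_end: Optional[int] = None
    if end_read.read_index == begin.read_index:
        end_contig_end = contig.length

    read_len_hint = max(len(r) for r in reads)
    wrap_extend = read_len_hint + 2 * s

    def extension_target() -> int:
        # the circle closes at contig coordinate ~len(reference) (the period);
        # extend past it so the origin junction is covered and detectable
        assert end_contig_end is not None
        closure = max(end_contig_end, len(reference))
        return closure + wrap_extend

    def try_locate_end() -> Optional[int]:
        placed = _place_on_tail(
            contig,
            _dna.encode(end_read.sequence),
            max_back=3 * read_len_hint,
            mismatch_rate=params.max_overlap_mismatch_rate * 2 + 0.02,
        )
        if placed is not None:
            return placed[0] + len(end_read.sequence)
        return None

    while True:
        if end_contig_end is not None and contig.length >= extension_target():
            break
        if contig.length > max_length:
            end_contig_end = end_contig_end or try_locate_end()
            if end_contig_end is not None:
                break
            raise RunawayAssemblyError(contig.length, max_length)

        # gather candidates whose seed matches near the contig tail
        tail_hi = contig.length - s
        tail_lo = max(0, tail_hi - params.tail_backoff)
        cand: dict[tuple[int, int], None] = {}
        # contig.seq stores codes, the index stores ASCII: translate once
        tail_ascii = _dna.decode(contig.seq[tail_lo : contig.length]).encode("ascii")
        for p in range(tail_hi, tail_lo - 1, -1):
            seed = tail_ascii[p - tail_lo : p - tail_lo + s]
            for oidx, off in table.get(seed, ()):
                if used[oidx // 2]:
                    continue
                start = p - off
                if start < 0:
                    continue
                cand[(oidx, start)] = None

        best: Optional[tuple[int, int, int, int]] = None  # (overlap, mm, oidx, start)
        for oidx, start in cand:
            if used[oidx // 2]:
                continue
            rcodes = ocodes(oidx)
            n = rcodes.shape[0]
            overlap = contig.length - start
            if overlap < params.min_overlap:
                continue
            if overlap >= n:
                # fully contained: verify and absorb into the pileup
                mm = _dna.hamming(rcodes, contig.seq[start : start + n])
                if mm <= int(params.max_overlap_mismatch_rate * n):
                    contig.add(rcodes, start)
                    used[oidx // 2] = True
                    if oidx // 2 == end_read.read_index and end_contig_end is None:
                        end_contig_end = start + n
                continue
            mm = _dna.hamming(rcodes[:overlap], contig.seq[start : contig.length])
            if mm > int(params.max_overlap_mismatch_rate * overlap):
                continue
            key = (overlap, mm, oidx)
            if (
                best is None
                or overlap > best[0]
                or (overlap == best[0] and (mm, oidx) < (best[1], best[2]))
            ):
                best = (overlap, mm, oidx, start)

        if best is None:
            if end_contig_end is not None:
                break  # circle closed; nothing left past the junction
            located = try_locate_end()
            if located is not None:
                end_contig_end = located
                break
            raise AssemblyGapError(contig.length)

        _, _, oidx, start = best
        contig.add(ocodes(oidx), start)
        used[oidx // 2] = True
        if oidx // 2 == end_read.read_index and end_contig_end is None:
            end_contig_end = start + ocodes(oidx).shape[0]

    assert end_contig_end is not None
    period = _detect_period(contig, reference, anchors, params)
    if period is None:
        period = end_contig_end
    else:
        # fold wrapped columns back onto the start of the circle
        width = min(contig.length - period, period)
        if width > 0:
            contig.counts[:, :width] += contig.counts[:, period : period + width]
    if abs(period - len(reference)) > params.length_tolerance:
        raise ConsensusError(
            f"assembled length {period} outside tolerance band "
            f"{len(reference)}±{params.length_tolerance}"
        )
    counts = contig.counts[:, :period]
    support = counts.sum(axis=0)
    if np.any(support == 0):
        gap = int(np.argmin(support > 0))
        raise AssemblyGapError(gap, f"assembly gap: no support at position {gap}")
    codes = np.argmax(counts, axis=0).astype(np.uint8)
    # rotate so position 0 is the reference origin
    codes = np.roll(codes, anchors.begin_offset)
    support = np.roll(support, anchors.begin_offset)
    consensus = MitoConsensus(sequence=_dna.decode(codes), per_base_support=support)
    logger.info(
        "assembled consensus: %d bp, mean support %.1fx",
        consensus.length_bp,
        consensus.mean_support(),
    )
    return consensus


def _detect_period(
    contig: _Contig,
    reference: ReferenceMito,
    anchors: AnchorReads,
    params: TypingParams,
    probe_len: int = 40,
    probe_tol: int = 6,
) -> Optional[int]:
    """Find the circle length as the second occurrence of the contig head."""
    m_ref = len(reference)
    lo = max(probe_len, m_ref - params.length_tolerance)
    hi = min(contig.length - probe_len, m_ref + params.length_tolerance)
    if hi < lo:
        return None
    probe = contig.seq[:probe_len]
    best: Optional[tuple[int, int]] = None
    for q in range(lo, hi + 1):
        mm = _dna.hamming(probe, contig.seq[q : q + probe_len])
        if mm <= probe_tol and (best is None or mm < best[1]):
            best = (q, mm)
    return None if best is None else best[0]


def type_consensus(
    reads: Sequence[str],
    reference: ReferenceMito,
    params: TypingParams = TypingParams(),
    max_typing_reads: Optional[int] = 12000,
) -> MitoConsensus:
    """Convenience wrapper: screen -> anchor -> assemble."""
    pool = screen_reads(reads, reference, max_reads=max_typing_reads)
    logger.info("typing pool: %d candidate reads", len(pool))
    anchors = select_anchor_reads(pool, reference, params)
    return assemble_consensus(pool, anchors, reference, params)
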