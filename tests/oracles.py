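"""Independent brute-force oracles used to validate the package's fast paths.

These deliberately share no code with the implementation: the mapper
oracle is an exhaustive circular Hamming scan, the ANOVA oracle is the
textbook sum-of-squares computation, and the consensus oracle is a direct
per-position majority vote over true read placements.
"""

from __future__ import annotations

import numpy as np

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def exhaustive_placements(read: str, consensus: str, max_mismatches: int):
    """All (position, strand, mismatches) with mm <= max, by circular scan."""
    m = len(consensus)
    doubled = consensus * 2
    out = []
    for strand, q in (("+", read), ("-", rc(read))):
        for start in range(m):
            window = doubled[start : start + len(q)]
            mm = sum(1 for a, b in zip(q, window) if a != b)
            if mm <= max_mismatches:
                out.append((start, strand, mm))
    return out


def exhaustive_placements_np(read: str, consensus: str, max_mismatches: int):
    """Vectorized version of the circular Hamming-scan oracle.

    Same contract as :func:`exhaustive_placements`, but fast enough for
    hundreds of reads; built directly on numpy byte comparison, sharing no
    code with the package's mapper.
    """
    m = len(consensus)
    doubled = np.frombuffer((consensus * 2).encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(doubled, len(read))[:m]
    out = []
    for strand, q in (("+", read), ("-", rc(read))):
        qa = np.frombuffer(q.encode(), dtype=np.uint8)
        mm = np.count_nonzero(windows != qa[None, :], axis=1)
        for pos in np.nonzero(mm <= max_mismatches)[0]:
            out.append((int(pos), strand, int(mm[pos])))
    return out


def anova_by_sums_of_squares(groups):
    """Hand-computed one-way ANOVA F from raw sums of squares."""
    all_vals = [v for g in groups for v in g]
    n = len(all_vals)
    grand = sum(all_vals) / n
    ssb = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ssw = sum((v - sum(g) / len(g)) ** 2 for g in groups for v in g)
    dfb = len(groups) - 1
    dfw = n - len(groups)
    return (ssb / dfb) / (ssw / dfw), dfb, dfw


def majority_consensus(length: int, placed_reads):
    """Majority vote over (start, sequence) placements on a circle."""
    votes = [dict() for _ in range(length)]
    for start, seq in placed_reads:
        for i, base in enumerate(seq):
            pos = (start + i) % length
            votes[pos][base] = votes[pos].get(base, 0) + 1
    out = []
    for v in votes:
        if not v:
            raise ValueError("uncovered position")
        best = max(v.items(), key=lambda kv: (kv[1], -ord(kv[0])))
        out.append(best[0])
    return "".join(out)
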