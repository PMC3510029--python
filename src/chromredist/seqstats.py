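"""Sequence-composition metrics and the small statistics toolkit.

CpG-dinucleotide density matters here because a high density of
unmethylated CpG sites is the proposed recruiting signal for Polycomb at
transposons that gain H3K27me3 once CG methylation is lost.  Both base
composition (G+C fraction) and CpG-dinucleotide density are reported; the
dinucleotide metric is the default for gain-vs-stable transposon
comparisons.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import List, Sequence, Tuple

import numpy as np


def cg_density(sequence: str) -> Tuple[float, float]:
    """(gc_fraction, cpg_dinucleotide_density) over A/C/G/T/N sequence.

    N bases are excluded from both numerators and denominators; the
    dinucleotide denominator counts windows whose two bases are both
    non-N.
    """
    seq = sequence.upper()
    if not seq:
        raise ValueError("empty sequence")
    valid = [b for b in seq if b != "N"]
    if not valid:
        raise ValueError("sequence contains only N bases")
    gc = sum(b in "CG" for b in valid) / len(valid)
    if len(seq) < 2:
        return gc, 0.0
    windows = cpg = 0
    for a, b in zip(seq, seq[1:]):
        if a == "N" or b == "N":
            continue
        windows += 1
        if a == "C" and b == "G":
            cpg += 1
    return gc, (cpg / windows if windows else 0.0)


def wilcoxon_ranksum(x: Sequence[float], y: Sequence[float],
                     exact_limit: int = 12) -> Tuple[float, float]:
    """Two-tailed Wilcoxon rank-sum test; returns (rank sum of x, p).

    Midranks are used for ties.  For n+m <= ``exact_limit`` without ties the
    null distribution is enumerated exactly (two-tailed p doubles the
    smaller tail, capped at 1); otherwise a normal approximation with tie
    correction and a 0.5 continuity correction is used.  A fully tied pooled
    sample gives p = 1.
    """
    from scipy.stats import rankdata

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both samples must be non-empty")
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    w = float(ranks[:n].sum())
    has_ties = len(np.unique(pooled)) < n + m
    if not has_ties and n + m <= exact_limit:
        # enumerate all C(n+m, n) placements of x among the integer ranks
        total = lo = hi = 0
        for combo in itertools.combinations(range(1, n + m + 1), n):
            s = sum(combo)
            total += 1
            lo += s <= w
            hi += s >= w
        p = min(1.0, 2 * min(lo, hi) / total)
        return w, p
    mean = n * (n + m + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    N = n + m
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / (N * (N - 1))
    var = n * m / 12.0 * (N + 1 - tie_term)
    if var == 0:
        return w, 1.0
    from scipy.stats import norm
    delta = abs(w - mean)
    z = max(delta - 0.5, 0.0) / np.sqrt(var)
    return w, min(1.0, 2 * float(norm.sf(z)))


@dataclasses.dataclass
class BoxplotSummary:
    """Five-number summary: quartiles by linear interpolation, whiskers at
    the most extreme data points within 1.5 x IQR of the box edges."""

    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: List[float]
    n: int

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


def boxplot_summary(values: Sequence[float]) -> BoxplotSummary:
    v = np.asarray(values, float)
    if len(v) == 0:
        raise ValueError("need at least one value")
    q1, med, q3 = np.percentile(v, [25, 50, 75])  # linear interpolation
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    return BoxplotSummary(
        median=float(med), q1=float(q1), q3=float(q3),
        whisker_low=float(inside.min()), whisker_high=float(inside.max()),
        outliers=sorted(float(o) for o in v[(v < lo_fence) | (v > hi_fence)]),
        n=len(v))


def extract_sequence(genome: dict, chrom: str, start: int, end: int,
                     strand: str = "+") -> str:
    """Element sequence from a chrom->str genome dict; minus strand is
    reverse-complemented."""
    seq = genome[chrom][start:end]
    if strand == "-":
        comp = str.maketrans("ACGTN", "TGCAN")
        seq = seq.translate(comp)[::-1]
    return seq
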