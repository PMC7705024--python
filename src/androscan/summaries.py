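"""Closed-form desk checks: plastome arithmetic, proportions, coverage,
BUSCO percentages, the 1:1 sex-ratio test, and k-mer genome-size estimation.

Rounding throughout is half-away-from-zero at the requested number of
decimals, matching how percentages are conventionally printed (e.g.
79/303 -> 26.07 -> 26.1).
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np
from scipy import stats as _stats

from .types import ValidationError


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero (unlike banker's rounding)."""
    factor = 10.0 ** decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def quadripartite_total(lsc: int, ssc: int, ir: int) -> int:
    """Total plastome length LSC + SSC + 2*IR (IRa and IRb are equal)."""
    if lsc <= 0 or ssc <= 0 or ir <= 0:
        raise ValidationError("plastome region lengths must be positive")
    return lsc + ssc + 2 * ir


def proportion_pct(count: int, total: int, decimals: int = 1) -> float:
    """Percentage count/total, rounded half-away-from-zero."""
    if total <= 0:
        raise ValidationError("total must be positive")
    if not 0 <= count <= total:
        raise ValidationError("need 0 <= count <= total")
    return round_half_away(100.0 * count / total, decimals)


def class_ratio(pct_a: float, pct_b: float, decimals: int = 2) -> float:
    """Ratio of two percentages (e.g. nonsynonymous/synonymous), rounded."""
    if pct_b == 0:
        raise ValidationError("denominator percentage must be non-zero")
    return round_half_away(pct_a / pct_b, decimals)


def coverage_fold(total_bases: float, genome_size: float,
                  round_to_int: bool = False) -> float:
    """Sequencing depth as total bases over genome size."""
    if genome_size <= 0:
        raise ValidationError("genome size must be positive")
    fold = total_bases / genome_size
    return float(round_half_away(fold, 0)) if round_to_int else fold


def busco_pct(n_category: int, n_total: int, decimals: int = 1) -> float:
    """BUSCO category percentage of total groups searched."""
    if n_total <= 0:
        raise ValidationError("total BUSCO groups must be positive")
    if not 0 <= n_category <= n_total:
        raise ValidationError("need 0 <= n_category <= n_total")
    return round_half_away(100.0 * n_category / n_total, decimals)


def chisq_1to1(n_male: int, n_herm: int):
    """Pearson goodness-of-fit of offspring sex counts against 1:1.

    Returns (statistic, df, p).  The statistic reduces to
    2*(n_male - mean)^2 / mean with mean = (n_male + n_herm)/2.
    """
    if n_male < 0 or n_herm < 0:
        raise ValidationError("counts must be non-negative")
    total = n_male + n_herm
    if total < 2:
        raise ValidationError("need at least two offspring")
    stat, p = _stats.chisquare([n_male, n_herm])
    return float(stat), 1, float(p)


# ---------------------------------------------------------------------------
# k-mer genome size
# ---------------------------------------------------------------------------

def count_kmers(reads, k: int = 17) -> dict[int, int]:
    """k-mer multiplicity histogram {depth: number of distinct k-mers}."""
    if k <= 0:
        raise ValidationError("k must be positive")
    counts: Counter[str] = Counter()
    for read in reads:
        for i in range(len(read) - k + 1):
            counts[read[i:i + k]] += 1
    return dict(Counter(counts.values()))


def estimate_genome_size(histogram: dict[int, int], k: int = 17) -> float:
    """Genome size from a k-mer histogram by the peak-depth method.

    The error tail of a k-mer spectrum is the low-depth, monotonically
    decreasing head; its end is taken as the first depth after which the
    histogram rises (the valley).  The homozygous peak is the modal depth
    beyond the valley, and genome size = (total k-mers beyond the valley)
    / peak depth.
    """
    if not histogram:
        raise ValidationError("empty k-mer histogram")
    if any(d < 1 for d in histogram) or any(c < 0 for c in histogram.values()):
        raise ValidationError("histogram needs depths >= 1 and counts >= 0")
    max_d = max(histogram)
    dense = np.zeros(max_d + 1, dtype=float)
    for d, c in histogram.items():
        dense[d] = c
    first_nonzero = int(np.flatnonzero(dense)[0])
    rises = np.flatnonzero(dense[1:] > dense[:-1])  # depth d where c(d+1) > c(d)
    rises = rises[rises >= first_nonzero]
    if rises.size == 0:
        raise ValidationError(
            "no interior peak in k-mer histogram (monotone spectrum); "
            "more sequencing coverage is needed"
        )
    boundary = int(rises[0])
    tail = dense[boundary + 1:]
    peak_depth = boundary + 1 + int(np.argmax(tail))
    if dense[peak_depth] <= dense[boundary]:
        raise ValidationError("no interior peak above the error valley")
    total_kmers = float(np.sum(np.arange(boundary + 1, max_d + 1) * tail))
    return total_kmers / peak_depth
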