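"""Small-sample quantifications: labeled-cell fractions with Wilson CIs,
population composition, transcript-fraction partitioning, and growth-curve
doubling time.

Rounding follows round-half-to-even at the stated number of decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from statsmodels.stats.proportion import proportion_confint


@dataclass(frozen=True)
class CountPair:
    positive: int
    total: int

    def __post_init__(self):
        if not (0 <= self.positive <= self.total):
            raise ValueError("need 0 <= positive <= total")


@dataclass(frozen=True)
class LabeledFraction:
    percent: float
    ci_low: float
    ci_high: float
    positive: int
    total: int


def labeled_fraction(pair: CountPair, decimals: int = 1) -> LabeledFraction:
    """Percent positive with a Wilson score 95% confidence interval."""
    if pair.total == 0:
        raise ValueError("total must be positive")
    pct = round(100.0 * pair.positive / pair.total, decimals)
    lo, hi = proportion_confint(pair.positive, pair.total, alpha=0.05, method="wilson")
    return LabeledFraction(
        percent=pct,
        ci_low=100.0 * float(lo),
        ci_high=100.0 * float(hi),
        positive=pair.positive,
        total=pair.total,
    )


def composition(category_counts: Sequence[int]) -> list[int]:
    """Per-category percent of the total, rounded to the nearest whole
    percent. The rounded percents are reported as-is and may not sum to
    100."""
    counts = [int(c) for c in category_counts]
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    total = sum(counts)
    if total == 0:
        raise ValueError("all counts are zero")
    return [int(round(100.0 * c / total)) for c in counts]


def transcript_fractions(component_levels: Sequence[float]) -> list[float]:
    """Percent of the summed signal per component, to one decimal."""
    levels = [float(x) for x in component_levels]
    if any(x < 0 for x in levels):
        raise ValueError("levels must be non-negative")
    total = sum(levels)
    if total == 0:
        raise ValueError("zero total signal")
    return [round(100.0 * x / total, 1) for x in levels]


def doubling_time(timepoints_hr: Sequence[float], counts: Sequence[float]) -> float | None:
    """Doubling time in hours from a cumulative growth series.

    Least-squares slope b of log2(count) against time over all points;
    doubling time = 1/b. Returns None (undefined) for non-growing series
    (b ≤ 0).
    """
    t = np.asarray(timepoints_hr, dtype=float)
    y = np.asarray(counts, dtype=float)
    if len(t) < 2:
        raise ValueError("need at least 2 timepoints")
    if np.any(np.diff(t) <= 0):
        raise ValueError("timepoints must be strictly increasing")
    if np.any(y <= 0):
        raise ValueError("counts must be positive")
    b = np.polyfit(t, np.log2(y), 1)[0]
    if b <= 1e-9:  # flat or shrinking: doubling time undefined
        return None
    return float(1.0 / b)
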