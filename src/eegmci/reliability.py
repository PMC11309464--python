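"""Effect sizes, correlations, test-retest consistency (Cronbach-alpha ICC)
and the prognostic quadrant summary."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["PairedMeasurements", "hedges_g", "icc_alpha", "pearson_r",
           "prognostic_quadrants"]


@dataclass
class PairedMeasurements:
    """Matched per-subject values at two visits (same units)."""

    subjects: np.ndarray
    visit1: np.ndarray
    visit2: np.ndarray

    def __post_init__(self) -> None:
        self.visit1 = np.asarray(self.visit1, dtype=float)
        self.visit2 = np.asarray(self.visit2, dtype=float)
        self.subjects = np.asarray(self.subjects)
        if not (len(self.subjects) == self.visit1.size == self.visit2.size):
            raise ValueError("paired measurements must have equal lengths")
        if self.visit1.size < 3:
            raise ValueError("need at least 3 matched subjects")


def hedges_g(sample_a: np.ndarray, sample_b: np.ndarray) -> float:
    """Bias-corrected standardised mean difference (a minus b).

    g = J * (mean_a - mean_b) / s_pooled with the pooled SD over both
    samples and the small-sample correction J = 1 - 3 / (4(n_a + n_b) - 9).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    n_a, n_b = a.size, b.size
    if n_a < 2 or n_b < 2:
        raise ValueError("need at least 2 observations per sample")
    sp2 = ((n_a - 1) * a.var(ddof=1) + (n_b - 1) * b.var(ddof=1)) / (n_a + n_b - 2)
    if sp2 <= 0:
        raise ValueError("zero pooled variance")
    j = 1.0 - 3.0 / (4.0 * (n_a + n_b) - 9.0)
    return float(j * (a.mean() - b.mean()) / np.sqrt(sp2))


def icc_alpha(paired: PairedMeasurements) -> float:
    """Test-retest consistency as Cronbach's alpha over the two visits.

    For k = 2 measurements, alpha = 2 * (1 - (s1^2 + s2^2) / s_sum^2) where
    s_sum^2 is the variance of per-subject sums; algebraically the k-item
    Cronbach formula at k = 2, and equivalent to the consistency-type
    ICC(3,k).
    """
    s1 = paired.visit1.var(ddof=1)
    s2 = paired.visit2.var(ddof=1)
    s_sum = (paired.visit1 + paired.visit2).var(ddof=1)
    if s_sum <= 0:
        raise ValueError("zero total variance")
    return float(2.0 * (1.0 - (s1 + s2) / s_sum))


def pearson_r(paired: PairedMeasurements) -> tuple[float, float]:
    """Sample Pearson correlation between visits with a two-sided t-based p."""
    if np.std(paired.visit1) == 0 or np.std(paired.visit2) == 0:
        raise ValueError("zero variance in one visit")
    res = stats.pearsonr(paired.visit1, paired.visit2)
    return float(res.statistic), float(res.pvalue)


def prognostic_quadrants(baseline_scores: np.ndarray,
                         outcome_change: np.ndarray,
                         decline_threshold: float = 0.0) -> dict:
    """Cross-tabulate baseline classification against subsequent decline.

    Quadrants: Q1 classified healthy (score <= 0), no decline; Q2 healthy,
    declined; Q3 classified MCI (score > 0), declined; Q4 MCI, no decline.
    Decline means the outcome change falls below ``decline_threshold``
    (default: any negative change).  Returns quadrant fractions (summing to
    1), counts, and the Pearson correlation between score and change.
    """
    score = np.asarray(baseline_scores, dtype=float)
    change = np.asarray(outcome_change, dtype=float)
    if score.size == 0 or score.size != change.size:
        raise ValueError("scores and outcomes must be non-empty and matched")
    mci = score > 0
    decline = change < decline_threshold
    counts = {
        "Q1": int(np.sum(~mci & ~decline)),
        "Q2": int(np.sum(~mci & decline)),
        "Q3": int(np.sum(mci & decline)),
        "Q4": int(np.sum(mci & ~decline)),
    }
    n = score.size
    fractions = {k: v / n for k, v in counts.items()}
    if np.std(score) > 0 and np.std(change) > 0:
        r, p = stats.pearsonr(score, change)
    else:
        r, p = float("nan"), float("nan")
    return {"fractions": fractions, "counts": counts, "n": n,
            "r": float(r), "p": float(p)}
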