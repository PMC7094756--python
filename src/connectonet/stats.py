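"""Closed-form statistical primitives shared by every analysis stage.

The edge-wise group comparisons, the network-based statistic, and the
classifier's feature screen all reduce to the same handful of tests:
pooled-variance two-sample t, paired t, the Fisher r-to-z transform that
stabilises correlation variance before testing, and an empirical
(permutation) p-value.  They live here once, in both scalar and
vectorised form, so every stage provably uses the same arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import (
    DegenerateVarianceError,
    EmptyNullError,
    InvalidSampleSizeError,
    LengthMismatchError,
)

__all__ = [
    "TestResult",
    "SummaryStats",
    "summaries",
    "pooled_two_sample_t",
    "two_sample_t",
    "paired_t",
    "fisher_r_to_z",
    "inverse_fisher_z",
    "empirical_p",
    "pooled_t_stats",
    "paired_t_stats",
]

#: Correlations are clamped to 1 - FISHER_CLAMP in magnitude before the
#: r-to-z transform so degenerate (|r| = 1) edges stay finite.
FISHER_CLAMP = 1e-7


@dataclass(frozen=True)
class TestResult:
    """Outcome of a hypothesis test.

    ``statistic`` is a t (or chi-square) value, ``df`` its degrees of
    freedom and ``p_value`` the tail probability for the given ``tail``.
    """

    statistic: float
    df: float
    p_value: float
    tail: str = "two_sided"


@dataclass(frozen=True)
class SummaryStats:
    """Printed-table summary of one sample: mean, sample SD and n."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise InvalidSampleSizeError(f"need n >= 2, got n={self.n}")
        if self.sd < 0:
            raise ValueError(f"sd must be non-negative, got {self.sd}")


def summaries(x: Sequence[float]) -> SummaryStats:
    """Summarise a sample as (mean, sample SD, n)."""
    arr = np.asarray(x, dtype=float)
    if arr.size < 2:
        raise InvalidSampleSizeError(f"need n >= 2, got n={arr.size}")
    return SummaryStats(float(arr.mean()), float(arr.std(ddof=1)), int(arr.size))


def pooled_two_sample_t(a: SummaryStats, b: SummaryStats) -> TestResult:
    """Student's pooled-variance two-sample t-test from summary statistics.

    df = n_a + n_b - 2.  The pooled form (not Welch) is used throughout:
    it is what printed demographic tables of this kind report.
    """
    df = a.n + b.n - 2
    pooled_var = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
    if pooled_var == 0.0:
        if a.mean == b.mean:
            return TestResult(0.0, float(df), 1.0)
        raise DegenerateVarianceError(
            "pooled variance is zero but group means differ"
        )
    se = np.sqrt(pooled_var * (1.0 / a.n + 1.0 / b.n))
    t = (a.mean - b.mean) / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(float(t), float(df), float(p))


def two_sample_t(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Pooled two-sample t-test on raw samples (group x minus group y)."""
    return pooled_two_sample_t(summaries(x), summaries(y))


def paired_t(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Paired t-test: one-sample t on the differences d = x - y, df = n - 1.

    When every difference is identical and nonzero the statistic is
    flagged as +/-inf (p = 0) rather than raising: downstream permutation
    machinery treats it as an extreme but valid value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise LengthMismatchError(f"paired lengths differ: {x.size} vs {y.size}")
    if x.size < 2:
        raise InvalidSampleSizeError(f"need n >= 2 pairs, got {x.size}")
    d = x - y
    n = d.size
    df = n - 1
    sd = d.std(ddof=1)
    mean = d.mean()
    if sd == 0.0:
        if mean == 0.0:
            return TestResult(0.0, float(df), 1.0)
        return TestResult(float(np.sign(mean) * np.inf), float(df), 0.0)
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(float(t), float(df), float(p))


def fisher_r_to_z(r):
    """Variance-stabilising Fisher transform z = arctanh(r).

    Accepts scalars or arrays.  Values with |r| >= 1 - 1e-7 are clamped
    so self-correlations and numerically saturated edges stay finite.
    """
    r = np.asarray(r, dtype=float)
    clipped = np.clip(r, -1.0 + FISHER_CLAMP, 1.0 - FISHER_CLAMP)
    z = np.arctanh(clipped)
    return float(z) if z.ndim == 0 else z


def inverse_fisher_z(z):
    """Inverse of :func:`fisher_r_to_z`: r = tanh(z)."""
    r = np.tanh(np.asarray(z, dtype=float))
    return float(r) if r.ndim == 0 else r


def empirical_p(observed: float, null_samples: Sequence[float]) -> float:
    """Permutation p-value with the add-one estimator (1 + b) / (1 + M).

    b counts null samples >= observed (ties count against the observed
    value, the conservative convention).  The estimator never returns 0
    and is bounded below by 1/(M + 1).
    """
    null = np.asarray(null_samples, dtype=float)
    if null.size == 0:
        raise EmptyNullError("empirical p-value needs at least one null sample")
    b = int(np.count_nonzero(null >= observed))
    return (1 + b) / (1 + null.size)


# ---------------------------------------------------------------------------
# Vectorised forms used by the edge-wise and permutation machinery.  These
# compute one t per column and must agree with the scalar tests above to
# floating-point accuracy (asserted in the test suite).


def pooled_t_stats(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Column-wise pooled two-sample t for matrices (subjects x features).

    Columns with zero pooled variance yield t = 0 when the means agree
    and +/-inf otherwise (no exception: used inside permutation loops).
    Returns (t_vector, df).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.shape[0], y.shape[0]
    if n1 < 2 or n2 < 2:
        raise InvalidSampleSizeError("need >= 2 subjects per group")
    df = n1 + n2 - 2
    m1, m2 = x.mean(axis=0), y.mean(axis=0)
    sv = ((n1 - 1) * x.var(axis=0, ddof=1) + (n2 - 1) * y.var(axis=0, ddof=1)) / df
    se = np.sqrt(sv * (1.0 / n1 + 1.0 / n2))
    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
        t = np.where(se == 0.0, np.where(diff == 0.0, 0.0, np.sign(diff) * np.inf), t)
    return t, float(df)


def paired_t_stats(d: np.ndarray) -> tuple[np.ndarray, float]:
    """Column-wise one-sample t on difference matrices (subjects x features)."""
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if n < 2:
        raise InvalidSampleSizeError("need >= 2 pairs")
    m = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (sd / np.sqrt(n))
        t = np.where(sd == 0.0, np.where(m == 0.0, 0.0, np.sign(m) * np.inf), t)
    return t, float(n - 1)
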