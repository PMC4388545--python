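"""Rater-reliability and association statistics.

Covers exactly the statistics the tilt pipeline reports:

* the intraclass correlation under a two-way model for absolute agreement
  (McGraw & Wong ICC(A,1) single-measures, with the average-measures
  variant also available), with its F-based 95% confidence interval and
  p-value — absolute agreement penalizes systematic offsets between
  raters, unlike the consistency ICC;
* Spearman's rank correlation with mid-ranks for ties, p-value from the
  t approximation (exact permutation available for small n);
* mean / SD / range column summaries.

The ICC is computed from the standard two-way ANOVA decomposition by the
defining formula

    ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

with the F-based confidence interval of McGraw & Wong (Satterthwaite
degrees of freedom) and the subject-variance F test for the p-value; the
mean squares are reported so results can be audited. (The point estimate
and interval agree with ``pingouin.intraclass_corr``, which however
rounds its interval to two decimals — too coarse for reliabilities in
the 0.95+ range.)
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy import stats

__all__ = [
    "RatingMatrix",
    "ICCResult",
    "CorrelationResult",
    "icc_absolute_agreement",
    "spearman",
    "summarize",
]


@dataclass(frozen=True)
class RatingMatrix:
    """n subjects x k raters measurement matrix (no missing cells)."""

    values: np.ndarray
    subject_ids: tuple = ()
    rater_ids: tuple = ()

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 2:
            raise ValueError("values must be a 2-D (subjects x raters) array")
        n, k = vals.shape
        if n < 2 or k < 2:
            raise ValueError(f"need at least 2 subjects and 2 raters, got {n} x {k}")
        if not np.all(np.isfinite(vals)):
            raise ValueError("ratings must be finite (apply listwise deletion upstream)")
        if not self.subject_ids:
            object.__setattr__(self, "subject_ids", tuple(range(n)))
        if not self.rater_ids:
            object.__setattr__(self, "rater_ids", tuple(range(k)))
        if len(self.subject_ids) != n or len(self.rater_ids) != k:
            raise ValueError("id lengths must match the matrix shape")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ICCResult:
    """Absolute-agreement ICC with 95% CI, ANOVA mean squares and F-test p."""

    icc: float
    ci_lower: float
    ci_upper: float
    ms_rows: float
    ms_cols: float
    ms_error: float
    p_value: float
    n: int
    k: int
    measures: str = "single"

    def __post_init__(self) -> None:
        if not (self.ci_lower <= self.icc <= self.ci_upper + 1e-12):
            raise ValueError("CI must bracket the estimate")
        if self.icc > 1 + 1e-12:
            raise ValueError("ICC cannot exceed 1")


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if abs(self.rho) > 1 + 1e-12:
            raise ValueError("|rho| cannot exceed 1")


def _mean_squares(vals: np.ndarray) -> tuple[float, float, float]:
    """Two-way ANOVA mean squares (rows=subjects, cols=raters)."""
    n, k = vals.shape
    grand = vals.mean()
    row_means = vals.mean(axis=1)
    col_means = vals.mean(axis=0)
    ssr = k * float(np.sum((row_means - grand) ** 2))
    ssc = n * float(np.sum((col_means - grand) ** 2))
    sst = float(np.sum((vals - grand) ** 2))
    sse = sst - ssr - ssc
    return ssr / (n - 1), ssc / (k - 1), sse / ((n - 1) * (k - 1))


def _agreement_ci(icc1: float, msr: float, msc: float, mse: float, n: int, k: int,
                  alpha: float = 0.05) -> tuple[float, float]:
    """McGraw & Wong F-based CI for the single-measures agreement ICC."""
    a = k * icc1 / (n * (1.0 - icc1))
    b = 1.0 + k * icc1 * (n - 1.0) / (n * (1.0 - icc1))
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1.0) + (b * mse) ** 2 / ((n - 1.0) * (k - 1.0))
    )
    f_lo = stats.f.ppf(1.0 - alpha / 2.0, n - 1.0, v)
    f_up = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1.0)
    lower = n * (msr - f_lo * mse) / (f_lo * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f_up * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_up * msr)
    return float(lower), float(upper)


def icc_absolute_agreement(ratings: RatingMatrix, measures: str = "single") -> ICCResult:
    """Two-way absolute-agreement intraclass correlation.

    Parameters
    ----------
    ratings : RatingMatrix
        Complete n x k measurements.
    measures : {'single', 'average'}
        Single-rating ICC(A,1) (default, the headline statistic) or the
        average-of-k ICC(A,k).

    Returns
    -------
    ICCResult
        Point estimate with 95% CI, the three ANOVA mean squares, and the
        p-value of the subject-variance F test (``MSR/MSE`` on ``n-1`` and
        ``(n-1)(k-1)`` degrees of freedom).

    Raises
    ------
    ValueError
        If the matrix has zero total variance (ICC undefined).
    """
    if measures not in ("single", "average"):
        raise ValueError(f"unknown measures {measures!r}")
    vals = ratings.values
    if float(np.var(vals)) == 0.0:
        raise ValueError("zero total variance: ICC undefined")
    n, k = vals.shape
    msr, msc, mse = _mean_squares(vals)

    icc1 = (msr - mse) / (msr + (k - 1.0) * mse + (k / n) * (msc - mse))
    if mse == 0.0 and msc == 0.0:
        # exact agreement: estimate and interval collapse at 1
        icc1, lo1, up1, p = 1.0, 1.0, 1.0, 0.0
    else:
        lo1, up1 = _agreement_ci(icc1, msr, msc, mse, n, k)
        p = float(stats.f.sf(msr / mse, n - 1, (n - 1) * (k - 1))) if mse > 0 else 0.0
    if measures == "single":
        icc, lo, up = icc1, lo1, up1
    else:
        # Spearman-Brown step-up of the single-measures quantities
        def up_k(r: float) -> float:
            return k * r / (1.0 + (k - 1.0) * r)

        icc = (msr - mse) / (msr + (msc - mse) / n) if mse or msc else 1.0
        lo, up = up_k(lo1), up_k(up1)
    icc = min(icc, 1.0)
    return ICCResult(
        icc=float(icc),
        ci_lower=float(min(lo, icc)),
        ci_upper=float(min(up, 1.0)),
        ms_rows=msr,
        ms_cols=msc,
        ms_error=mse,
        p_value=p,
        n=n,
        k=k,
        measures=measures,
    )


def spearman(x, y, method: str = "t") -> CorrelationResult:
    """Spearman rank correlation with mid-ranks for ties.

    ``rho`` is the Pearson correlation of average ranks. The p-value uses
    the two-sided t approximation ``t = rho*sqrt((n-2)/(1-rho^2))`` on
    ``n - 2`` degrees of freedom (``method='t'``), or the exact two-sided
    permutation distribution for ``method='exact'`` (n <= 10 only).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs for a Spearman p-value")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: ranks are degenerate")
    if method == "t":
        rho, p = stats.spearmanr(x, y)
        return CorrelationResult(rho=float(rho), p_value=float(p), n=n)
    if method != "exact":
        raise ValueError(f"unknown method {method!r}")
    if n > 10:
        raise ValueError("exact permutation p-value supported only for n <= 10")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho_obs = float(np.corrcoef(rx, ry)[0, 1])
    # exact null: all pairings of the observed rank vectors
    rxc = rx - rx.mean()
    sx = math.sqrt(float(rxc @ rxc))
    ryc = ry - ry.mean()
    sy = math.sqrt(float(ryc @ ryc))
    count = 0
    total = 0
    for perm in permutations(ryc):
        r = float(rxc @ np.asarray(perm)) / (sx * sy)
        if abs(r) >= abs(rho_obs) - 1e-12:
            count += 1
        total += 1
    return CorrelationResult(rho=rho_obs, p_value=count / total, n=n)


def summarize(values) -> dict:
    """Mean, sample SD (n-1 denominator), min and max of a numeric vector."""
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < 2:
        raise ValueError("need at least 2 finite values to summarize")
    return {
        "mean": float(vals.mean()),
        "sd": float(vals.std(ddof=1)),
        "min": float(vals.min()),
        "max": float(vals.max()),
        "n": int(vals.size),
    }
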