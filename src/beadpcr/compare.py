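"""Method-comparison statistics for paired concentration measurements.

Digital-PCR platforms are compared on the log10 concentration scale:
Deming regression (errors-in-variables, both methods noisy), Pearson
correlation, Bland-Altman agreement, and per-level replicate precision
(SD of log10 concentrations with zero-result replicates accounted
separately).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "PairedMeasurements",
    "ComparisonReport",
    "deming",
    "bland_altman",
    "replicate_precision",
    "compare_methods",
]


@dataclass
class PairedMeasurements:
    """Paired (method_x, method_y) values per level, optionally log10."""

    x: np.ndarray
    y: np.ndarray
    levels: list[str] | None = None
    log10_applied: bool = False

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float).ravel()
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have equal length")

    def to_log10(self) -> "PairedMeasurements":
        if self.log10_applied:
            return self
        if np.any(self.x <= 0) or np.any(self.y <= 0):
            raise ValueError("values must be positive before log10 transform")
        return PairedMeasurements(
            np.log10(self.x), np.log10(self.y), self.levels, True
        )


@dataclass
class ComparisonReport:
    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    pearson_r: float
    pearson_p: float
    mean_difference: float
    loa: tuple[float, float]
    n: int
    extras: dict = field(default_factory=dict)


def _deming_point(x: np.ndarray, y: np.ndarray, variance_ratio: float):
    """Closed-form Deming estimator.

    ``variance_ratio`` is the ratio of the y-error variance to the
    x-error variance (lambda); 1 gives orthogonal regression.
    """
    n = x.size
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum()) / (n - 1)
    syy = float(((y - ym) ** 2).sum()) / (n - 1)
    sxy = float(((x - xm) * (y - ym)).sum()) / (n - 1)
    lam = variance_ratio
    if sxy == 0.0:
        if sxx == 0.0 and syy == 0.0:
            raise ValueError("zero variance in both x and y")
        # no covariance: vertical/horizontal degeneracy; slope 0
        return 0.0, ym
    slope = (syy - lam * sxx + math.sqrt((syy - lam * sxx) ** 2 + 4 * lam * sxy**2)) / (
        2 * sxy
    )
    return slope, ym - slope * xm


def deming(
    data: PairedMeasurements,
    variance_ratio: float = 1.0,
    *,
    ci_method: str = "jackknife",
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, float, tuple[float, float], tuple[float, float]]:
    """Deming regression of method y on method x.

    Returns ``(slope, intercept, slope_ci95, intercept_ci95)``.  CIs by
    leave-one-out jackknife (default) or paired bootstrap.
    """
    x, y = data.x, data.y
    n = x.size
    if n < 3:
        raise ValueError("need >= 3 points for Deming regression")
    if variance_ratio <= 0:
        raise ValueError("variance_ratio must be positive")
    slope, intercept = _deming_point(x, y, variance_ratio)

    if ci_method == "jackknife":
        reps = np.array(
            [
                _deming_point(np.delete(x, i), np.delete(y, i), variance_ratio)
                for i in range(n)
            ]
        )
        # jackknife SE with t quantile
        mean_rep = reps.mean(axis=0)
        se = np.sqrt((n - 1) / n * ((reps - mean_rep) ** 2).sum(axis=0))
        q = stats.t.ppf(0.975, n - 2)
        slope_ci = (slope - q * se[0], slope + q * se[0])
        intercept_ci = (intercept - q * se[1], intercept + q * se[1])
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        reps = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            try:
                reps.append(_deming_point(x[idx], y[idx], variance_ratio))
            except ValueError:
                continue
        reps = np.asarray(reps)
        lo = np.percentile(reps, 2.5, axis=0)
        hi = np.percentile(reps, 97.5, axis=0)
        slope_ci, intercept_ci = (lo[0], hi[0]), (lo[1], hi[1])
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return (
        float(slope),
        float(intercept),
        (float(slope_ci[0]), float(slope_ci[1])),
        (float(intercept_ci[0]), float(intercept_ci[1])),
    )


def bland_altman(data: PairedMeasurements) -> tuple[float, tuple[float, float]]:
    """Mean difference (y - x) and 95% limits of agreement.

    Limits are ``mean +/- 1.96 * SD`` of the paired differences, on
    whatever scale the data carry (log10 for concentration comparisons).
    """
    if data.x.size < 2:
        raise ValueError("need >= 2 points")
    d = data.y - data.x
    m = float(d.mean())
    sd = float(d.std(ddof=1))
    return m, (m - 1.96 * sd, m + 1.96 * sd)


def replicate_precision(
    concentrations_per_level: dict[str, np.ndarray],
) -> dict[str, dict]:
    """Per-level precision: SD of log10 concentration over nonzero replicates.

    Replicates with a zero (or non-finite) result are excluded from the
    SD and counted separately — mirroring the accounting used when a
    heavily diluted level yields only a handful of nonzero replicates.
    """
    out = {}
    for level, vals in concentrations_per_level.items():
        v = np.asarray(vals, dtype=float).ravel()
        nonzero = v[np.isfinite(v) & (v > 0)]
        entry = {
            "n_total": int(v.size),
            "n_nonzero": int(nonzero.size),
        }
        if nonzero.size >= 2:
            entry["sd_log10"] = float(np.log10(nonzero).std(ddof=1))
        else:
            entry["sd_log10"] = None  # undefined with < 2 nonzero replicates
        out[level] = entry
    return out


def compare_methods(
    data: PairedMeasurements,
    variance_ratio: float = 1.0,
    *,
    ci_method: str = "jackknife",
) -> ComparisonReport:
    """Full comparison on the log10 scale: Deming + Pearson + Bland-Altman."""
    logged = data.to_log10()
    slope, intercept, s_ci, i_ci = deming(
        logged, variance_ratio, ci_method=ci_method
    )
    r, p = stats.pearsonr(logged.x, logged.y)
    md, loa = bland_altman(logged)
    return ComparisonReport(
        slope=slope,
        intercept=intercept,
        slope_ci=s_ci,
        intercept_ci=i_ci,
        pearson_r=float(r),
        pearson_p=float(p),
        mean_difference=md,
        loa=loa,
        n=int(logged.x.size),
    )
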