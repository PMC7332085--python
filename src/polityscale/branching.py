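"""Horton-Strahler branching analysis of population metrics across levels.

Population size N, geographic range A and density D = N/A are approximately
lognormal within each jurisdictional level, so the geometric mean
``exp(mean of logs)`` is the central tendency throughout. Self-similarity
across the hierarchy means the level-to-level ratio of geometric means (the
branching ratio R) is constant, equivalently that the mean logs are linear
in level w:

    mean ln X at level w+k = mean ln X at level w + rate * k,

with rate lam for N (R_N = exp(lam)), gamma for A (R_A = exp(gamma)) and
theta = lam - gamma for D. The rates are estimated by unweighted OLS of the
level mean logs on w, and self-similarity is judged by whether every level
mean falls inside the fit's 95% confidence band. Quantile regressions check
that the same log-linear growth holds beyond the mean, at any quantile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.regression.quantile_regression import QuantReg

from .io import SocietyTable

__all__ = [
    "LevelSummary",
    "HortonFit",
    "BetaPrediction",
    "LognormalityDiagnostic",
    "level_summaries",
    "branching_ratios_adjacent",
    "fit_horton_law",
    "density_fit",
    "predict_beta",
    "quantile_horton_fit",
    "lognormality_check",
]

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class LevelSummary:
    """Lognormal summary of one metric at one hierarchy level.

    ``geomean = exp(mean_log)`` exactly; the 95% confidence limits are
    ``exp(mean_log +/- 1.96 sd_log / sqrt(n))``. With a single record the
    sd is undefined and the limits collapse to the point value
    (``degenerate`` is set).
    """

    level: int
    metric: str
    n: int
    mean_log: float
    sd_log: float
    geomean: float
    cl_lower: float
    cl_upper: float
    degenerate: bool = False

    def to_row(self) -> dict:
        return {
            "level": self.level,
            "metric": self.metric,
            "n": self.n,
            "mean_log": self.mean_log,
            "sd_log": self.sd_log,
            "geomean": self.geomean,
            "cl_lower": self.cl_lower,
            "cl_upper": self.cl_upper,
        }


@dataclass
class HortonFit:
    """Semi-log OLS fit of level mean-logs on level.

    ``branching_ratio = exp(slope)`` exactly; its CI uses the t-quantile
    with (levels - 2) degrees of freedom on the slope SE. ``self_similar``
    records whether every level mean lies inside the 95% confidence band of
    the regression line.
    """

    metric: str
    slope: float
    slope_se: float
    intercept: float
    branching_ratio: float
    ratio_ci_lower: float
    ratio_ci_upper: float
    r_squared: float
    levels_used: tuple[int, ...]
    self_similar: bool

    def to_row(self) -> dict:
        return {
            "metric": self.metric,
            "slope": self.slope,
            "slope_se": self.slope_se,
            "intercept": self.intercept,
            "branching_ratio": self.branching_ratio,
            "ratio_ci_lower": self.ratio_ci_lower,
            "ratio_ci_upper": self.ratio_ci_upper,
            "r_squared": self.r_squared,
            "levels_used": "|".join(map(str, self.levels_used)),
            "self_similar": self.self_similar,
        }


@dataclass
class BetaPrediction:
    """Predicted allometric exponent beta = gamma / lam with delta-method SE."""

    beta: float
    se: float


@dataclass
class LognormalityDiagnostic:
    """Advisory normality diagnostics of the logged values at one level."""

    metric: str
    level: int
    n: int
    log_skewness: float
    log_excess_kurtosis: float
    normality_stat: float
    normality_pvalue: float
    sufficient_n: bool


def level_summaries(table: SocietyTable, metric: str) -> list[LevelSummary]:
    """Per-level lognormal summaries of metric 'N', 'A' or 'D'.

    One summary per level present, ordered by level; empty levels are simply
    absent, never zero-filled.
    """
    if len(table) == 0:
        raise ValueError("empty table")
    values = table.metric_values(metric)
    if (values <= 0).any():
        raise ValueError(f"metric {metric} has non-positive values")
    logs = np.log(values.to_numpy(dtype=float))
    lev = table.df["level"].to_numpy()
    out = []
    for w in sorted(np.unique(lev)):
        x = logs[lev == w]
        n = len(x)
        mean_log = float(np.mean(x))
        geomean = math.exp(mean_log)
        if n >= 2:
            sd_log = float(np.std(x, ddof=1))
            half = _Z95 * sd_log / math.sqrt(n)
            summary = LevelSummary(
                level=int(w),
                metric=metric,
                n=n,
                mean_log=mean_log,
                sd_log=sd_log,
                geomean=geomean,
                cl_lower=math.exp(mean_log - half),
                cl_upper=math.exp(mean_log + half),
            )
        else:
            summary = LevelSummary(
                level=int(w),
                metric=metric,
                n=n,
                mean_log=mean_log,
                sd_log=float("nan"),
                geomean=geomean,
                cl_lower=geomean,
                cl_upper=geomean,
                degenerate=True,
            )
        out.append(summary)
    return out


def branching_ratios_adjacent(
    summaries: Sequence[LevelSummary],
) -> list[tuple[int, int, float | None]]:
    """Ratios of geometric means between consecutive levels.

    Returns (lower level, upper level, ratio) for each adjacent pair of
    observed levels; a gap (missing intermediate level) yields a ``None``
    ratio for that pair rather than an interpolated value.
    """
    if len(summaries) < 2:
        raise ValueError("need at least 2 levels for branching ratios")
    ordered = sorted(summaries, key=lambda s: s.level)
    out: list[tuple[int, int, float | None]] = []
    for lo, hi in zip(ordered, ordered[1:]):
        if hi.level == lo.level + 1:
            out.append((lo.level, hi.level, hi.geomean / lo.geomean))
        else:
            out.append((lo.level, hi.level, None))
    return out


def fit_horton_law(
    summaries: Sequence[LevelSummary], weighted: bool = False
) -> HortonFit:
    """OLS of level mean-logs on level; exp(slope) is the branching ratio.

    Unweighted by default (one point per level); ``weighted`` uses the level
    sample sizes as WLS weights. Requires >= 3 levels with defined means.
    """
    usable = [s for s in sorted(summaries, key=lambda s: s.level)]
    if len(usable) < 3:
        raise ValueError("Horton fit requires at least 3 levels")
    w = np.array([s.level for s in usable], dtype=float)
    y = np.array([s.mean_log for s in usable])
    if np.ptp(w) == 0:
        raise ValueError("no variance in level")
    x = sm.add_constant(w)
    if weighted:
        model = sm.WLS(y, x, weights=[s.n for s in usable]).fit()
    else:
        model = sm.OLS(y, x).fit()
    slope = float(model.params[1])
    slope_se = float(model.bse[1])
    dof = len(usable) - 2
    tq = stats.t.ppf(0.975, dof)
    band = model.get_prediction(x).conf_int(alpha=0.05)
    inside = bool(np.all((y >= band[:, 0]) & (y <= band[:, 1])))
    return HortonFit(
        metric=usable[0].metric,
        slope=slope,
        slope_se=slope_se,
        intercept=float(model.params[0]),
        branching_ratio=math.exp(slope),
        ratio_ci_lower=math.exp(slope - tq * slope_se),
        ratio_ci_upper=math.exp(slope + tq * slope_se),
        r_squared=float(model.rsquared),
        levels_used=tuple(s.level for s in usable),
        self_similar=inside,
    )


def density_fit(
    fit_n: HortonFit,
    fit_a: HortonFit,
    summaries_d: Sequence[LevelSummary],
) -> HortonFit:
    """Direct Horton fit of density, checked against theta = lam - gamma.

    Because D = N/A per record, the level mean of ln D is exactly the
    difference of the level means of ln N and ln A, so the density rate
    theta must equal lam - gamma to numerical precision; this is asserted.
    """
    if fit_n.levels_used != fit_a.levels_used:
        raise ValueError("N and A fits use different level sets")
    fit_d = fit_horton_law(summaries_d)
    if fit_d.levels_used != fit_n.levels_used:
        raise ValueError("density summaries cover a different level set")
    expected = fit_n.slope - fit_a.slope
    if abs(fit_d.slope - expected) > 1e-9:
        raise AssertionError(
            f"density rate {fit_d.slope} != lam - gamma {expected}; "
            "density must be derived per-record from the same table"
        )
    return fit_d


def predict_beta(fit_n: HortonFit, fit_a: HortonFit) -> BetaPrediction:
    """Allometric exponent predicted from branching: beta = gamma / lam.

    The SE is first-order delta method treating the two slope estimates as
    independent.
    """
    lam, gamma = fit_n.slope, fit_a.slope
    if abs(lam) < 1e-12:
        raise ValueError("population rate lam is (numerically) zero; beta undefined")
    beta = gamma / lam
    se = math.sqrt(
        (fit_a.slope_se / lam) ** 2 + (gamma * fit_n.slope_se / lam**2) ** 2
    )
    return BetaPrediction(beta=beta, se=se)


def quantile_horton_fit(
    table: SocietyTable, metric: str, quantiles: Sequence[float]
) -> pd.DataFrame:
    """Per-quantile log-linear growth rates of a metric across levels.

    For each quantile q, fits a linear quantile regression (check loss) of
    ln(metric) on level and reports the slope. Under self-similarity all
    quantile slopes agree with the mean-based rate.
    """
    if len(list(quantiles)) == 0:
        raise ValueError("empty quantile list")
    if any(not 0.0 < q < 1.0 for q in quantiles):
        raise ValueError("quantiles must lie in (0, 1)")
    if table.df["level"].nunique() < 3:
        raise ValueError("quantile fits require at least 3 levels")
    y = np.log(table.metric_values(metric).to_numpy(dtype=float))
    x = sm.add_constant(table.df["level"].to_numpy(dtype=float))
    rows = []
    for q in quantiles:
        res = QuantReg(y, x).fit(q=q)
        rows.append(
            {
                "metric": metric,
                "quantile": q,
                "slope": float(res.params[1]),
                "intercept": float(res.params[0]),
            }
        )
    return pd.DataFrame(rows)


def lognormality_check(
    table: SocietyTable, metric: str, level: int
) -> LognormalityDiagnostic:
    """Advisory lognormality diagnostics for one metric at one level.

    Reports skewness, excess kurtosis and the D'Agostino-Pearson omnibus
    normality test on the logged values. Purely diagnostic: the pipeline
    never gates on this. Needs n >= 8 (the omnibus test is undefined below).
    """
    mask = table.df["level"] == level
    if not mask.any():
        raise ValueError(f"level {level} not present")
    logs = np.log(table.metric_values(metric).to_numpy(dtype=float)[mask])
    n = len(logs)
    if n < 8:
        return LognormalityDiagnostic(
            metric=metric,
            level=level,
            n=n,
            log_skewness=float("nan"),
            log_excess_kurtosis=float("nan"),
            normality_stat=float("nan"),
            normality_pvalue=float("nan"),
            sufficient_n=False,
        )
    stat, pval = stats.normaltest(logs)
    return LognormalityDiagnostic(
        metric=metric,
        level=level,
        n=n,
        log_skewness=float(stats.skew(logs)),
        log_excess_kurtosis=float(stats.kurtosis(logs)),
        normality_stat=float(stat),
        normality_pvalue=float(pval),
        sufficient_n=True,
    )
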