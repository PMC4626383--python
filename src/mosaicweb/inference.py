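"""Statistical layer over the per-unit metrics table.

Each network index is tested for altitude and time effects with one-way
ANOVA when its residuals pass normality (Shapiro-Wilk) and homogeneity
(Levene, mean-centered) at ``alpha_assume``, and with Kruskal-Wallis
otherwise.  Low-vs-high elevation contrasts use a pooled-variance t test
when Levene accepts homogeneity and Welch's t otherwise.  Polynomial fits
(degree 1 or 2) relate indices to altitude or precipitation, and the
individual-vs-cumulative comparison contrasts per-unit networks with the
spatially and temporally pooled ones.

No multiple-testing correction is applied across indices; each row of a
report is a marginal test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

ALPHA_ASSUME_DEFAULT = 0.05

#: indices compared between individual and cumulative networks
POOLING_METRICS = ["S", "M", "I", "L", "C", "NODF"]


@dataclass(frozen=True)
class FactorTestResult:
    metric: str
    factor: Literal["altitude", "time"]
    test_used: Literal["anova", "kruskal_wallis", "degenerate"]
    statistic: float
    p_value: float
    normality_p: float
    homogeneity_p: float


@dataclass(frozen=True)
class BandContrastResult:
    metric: str
    test_used: Literal["pooled_t", "welch_t", "degenerate"]
    statistic: float
    p_value: float
    levene_p: float
    mean_low: float
    se_low: float
    mean_high: float
    se_high: float


@dataclass(frozen=True)
class RegressionResult:
    response: str
    predictor: str
    degree: int
    coefficients: tuple[float, ...]  # intercept first
    r_squared: float
    f_statistic: float
    p_value: float
    curvature: Literal["concave", "convex", "none"]

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.polyval(self.coefficients[::-1], np.asarray(x, dtype=float))


def _groups(table: pd.DataFrame, metric: str, column: str) -> list[np.ndarray]:
    return [
        grp[metric].to_numpy(dtype=float)
        for _, grp in table.groupby(column, sort=True)
    ]


def factor_effects(
    metrics_table: pd.DataFrame,
    factor: Literal["altitude", "time"],
    metrics: Sequence[str] | None = None,
    alpha_assume: float = ALPHA_ASSUME_DEFAULT,
) -> list[FactorTestResult]:
    """Per-metric one-way test of a grid factor.

    Normality is assessed on the residuals from group means; routing is a
    pure function of the two assumption p-values.
    """
    column = "altitude" if factor == "altitude" else "month"
    if column not in metrics_table.columns:
        raise KeyError(f"metrics table lacks a {column!r} column")
    if metrics is None:
        metrics = [
            c for c in metrics_table.columns
            if c not in ("unit", "altitude", "month", "precipitation")
        ]
    level_sizes = metrics_table.groupby(column).size()
    if len(level_sizes) < 2 or (level_sizes < 2).any():
        raise ValueError("each factor level needs >= 2 observations")
    results = []
    for metric in metrics:
        groups = _groups(metrics_table, metric, column)
        values = np.concatenate(groups)
        if np.ptp(values) == 0:
            results.append(
                FactorTestResult(metric, factor, "degenerate",
                                 float("nan"), float("nan"),
                                 float("nan"), float("nan"))
            )
            continue
        residuals = np.concatenate([g - g.mean() for g in groups])
        if np.ptp(residuals) == 0:
            normality_p = 1.0
        else:
            normality_p = float(stats.shapiro(residuals).pvalue)
        homogeneity_p = float(stats.levene(*groups, center="mean").pvalue)
        if normality_p >= alpha_assume and homogeneity_p >= alpha_assume:
            stat, p = stats.f_oneway(*groups)
            test_used = "anova"
        else:
            stat, p = stats.kruskal(*groups)
            test_used = "kruskal_wallis"
        results.append(
            FactorTestResult(metric, factor, test_used, float(stat), float(p),
                             normality_p, homogeneity_p)
        )
    return results


def band_contrast(
    metrics_table: pd.DataFrame,
    boundary: int = 2700,
    metrics: Sequence[str] | None = None,
    alpha_assume: float = ALPHA_ASSUME_DEFAULT,
) -> list[BandContrastResult]:
    """Low (altitude <= boundary) vs high band contrast per metric."""
    if metrics is None:
        metrics = [
            c for c in metrics_table.columns
            if c not in ("unit", "altitude", "month", "precipitation")
        ]
    low = metrics_table[metrics_table["altitude"] <= boundary]
    high = metrics_table[metrics_table["altitude"] > boundary]
    if len(low) < 2 or len(high) < 2:
        raise ValueError("both elevation bands need >= 2 units")
    results = []
    for metric in metrics:
        x = low[metric].to_numpy(dtype=float)
        y = high[metric].to_numpy(dtype=float)
        summary = (
            float(x.mean()), float(stats.sem(x)),
            float(y.mean()), float(stats.sem(y)),
        )
        if np.ptp(np.concatenate([x, y])) == 0:
            results.append(
                BandContrastResult(metric, "degenerate", 0.0, 1.0,
                                   float("nan"), *summary)
            )
            continue
        levene_p = float(stats.levene(x, y, center="mean").pvalue)
        equal_var = levene_p >= alpha_assume
        stat, p = stats.ttest_ind(x, y, equal_var=equal_var)
        results.append(
            BandContrastResult(
                metric, "pooled_t" if equal_var else "welch_t",
                float(stat), float(p), levene_p, *summary,
            )
        )
    return results


def fit_polynomial(
    response: np.ndarray,
    predictor: np.ndarray,
    degree: Literal[1, 2] = 1,
    response_name: str = "y",
    predictor_name: str = "x",
) -> RegressionResult:
    """OLS on a raw polynomial basis with the overall F test."""
    y = np.asarray(response, dtype=float)
    x = np.asarray(predictor, dtype=float)
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    if len(y) != len(x):
        raise ValueError("response and predictor must share length")
    if len(y) <= degree + 1:
        raise ValueError(f"need more than {degree + 1} observations")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor")
    design = np.column_stack([x ** k for k in range(degree + 1)])
    if np.linalg.matrix_rank(design) <= degree:
        raise ValueError("collinear polynomial basis")
    fit = sm.OLS(y, design).fit()
    curvature: str = "none"
    if degree == 2:
        quad = fit.params[2]
        curvature = "concave" if quad < 0 else ("convex" if quad > 0 else "none")
    return RegressionResult(
        response=response_name,
        predictor=predictor_name,
        degree=degree,
        coefficients=tuple(float(b) for b in fit.params),
        r_squared=float(fit.rsquared),
        f_statistic=float(fit.fvalue),
        p_value=float(fit.f_pvalue),
        curvature=curvature,  # type: ignore[arg-type]
    )


def individual_vs_cumulative(
    metrics_individual: pd.DataFrame,
    metrics_cumulative_altitude: pd.DataFrame,
    metrics_cumulative_time: pd.DataFrame,
    metrics: Sequence[str] = tuple(POOLING_METRICS),
) -> pd.DataFrame:
    """Kruskal-Wallis across individual / altitude-pooled / time-pooled
    networks per metric, with group means and standard errors."""
    groups = {
        "individual": metrics_individual,
        "cumulative_altitude": metrics_cumulative_altitude,
        "cumulative_time": metrics_cumulative_time,
    }
    for name, table in groups.items():
        if len(table) == 0:
            raise ValueError(f"group {name!r} is empty")
    rows = []
    for metric in metrics:
        samples = [t[metric].to_numpy(dtype=float) for t in groups.values()]
        if np.ptp(np.concatenate(samples)) == 0:
            stat, p = float("nan"), 1.0
        else:
            stat, p = stats.kruskal(*samples)
        row = {"metric": metric, "chi2": float(stat), "p": float(p)}
        for name, values in zip(groups, samples):
            row[f"mean_{name}"] = float(np.mean(values))
            row[f"se_{name}"] = float(stats.sem(values)) if len(values) > 1 else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def factor_table(results: Sequence[FactorTestResult]) -> pd.DataFrame:
    """ANOVA/Kruskal-Wallis report, one row per (metric, factor)."""
    return pd.DataFrame(
        [
            {
                "metric": r.metric,
                "factor": r.factor,
                "test": r.test_used,
                "statistic": r.statistic,
                "p": r.p_value,
                "normality_p": r.normality_p,
                "homogeneity_p": r.homogeneity_p,
            }
            for r in results
        ]
    )


def band_table(results: Sequence[BandContrastResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "metric": r.metric,
                "test": r.test_used,
                "t": r.statistic,
                "p": r.p_value,
                "levene_p": r.levene_p,
                "mean_low": r.mean_low,
                "se_low": r.se_low,
                "mean_high": r.mean_high,
                "se_high": r.se_high,
            }
            for r in results
        ]
    )
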