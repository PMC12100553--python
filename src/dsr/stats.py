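"""Statistical battery for the DSR analyses.

Thin, explicit wrappers over scipy/statsmodels that fix the conventions
used throughout the package: Spearman rank correlation with midrank ties
and Fisher-z 95% confidence intervals; Bonferroni adjustment with an
explicit family size m at every call site (the analyses never infer m
silently); Kruskal-Wallis with tie correction; ordinary least squares
with declared reference levels for categorical predictors and
tolerance-based collinearity screening (tolerance = 1 - R^2 of each
predictor regressed on the others; values below 0.1 are flagged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationResult",
    "GroupTestResult",
    "RegressionTerm",
    "RegressionResult",
    "bonferroni",
    "spearman_bonferroni",
    "kruskal_wallis_by",
    "fit_linear_model",
    "shapiro_report",
]

TOLERANCE_WARN = 0.1


def bonferroni(p_raw: float, m: int) -> float:
    """Bonferroni-adjusted p-value: min(1, m * p)."""
    if m < 1:
        raise ValueError("family size m must be >= 1")
    return min(1.0, m * p_raw)


@dataclass(frozen=True)
class CorrelationResult:
    x_label: str
    y_label: str
    rho: float
    ci95: tuple[float, float]
    p_raw: float
    p_adjusted: float
    n: int


@dataclass(frozen=True)
class GroupTestResult:
    grouping: str
    h_statistic: float
    df: int
    p_raw: float
    p_adjusted: float


@dataclass(frozen=True)
class RegressionTerm:
    term: str
    estimate: float
    se: float
    t_value: float
    p_value: float


@dataclass(frozen=True)
class RegressionResult:
    outcome: str
    terms: tuple[RegressionTerm, ...]
    f_statistic: float
    f_pvalue: float
    r_squared: float
    n: int
    tolerance: Mapping[str, float] = field(default_factory=dict)

    def term(self, name: str) -> RegressionTerm:
        for t in self.terms:
            if t.term == name:
                return t
        raise KeyError(name)


def _fisher_ci(rho: float, n: int) -> tuple[float, float]:
    if n <= 3 or abs(rho) >= 1.0:
        return (rho, rho)
    z = np.arctanh(rho)
    half = 1.959963984540054 / np.sqrt(n - 3)
    return (float(np.tanh(z - half)), float(np.tanh(z + half)))


def spearman_bonferroni(
    pairs: Sequence[tuple[np.ndarray, np.ndarray]],
    m: int,
    labels: Sequence[tuple[str, str]] | None = None,
) -> list[CorrelationResult]:
    """Spearman rho (midrank ties) with Fisher-z 95% CI, Bonferroni m.

    Each pair must have equal-length vectors with n >= 3 and neither
    vector constant (rank correlation is undefined for a constant).
    """
    if labels is None:
        labels = [(f"x{i}", f"y{i}") for i in range(len(pairs))]
    out = []
    for (x, y), (xl, yl) in zip(pairs, labels, strict=True):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("pair vectors must be 1-D and equal length")
        n = len(x)
        if n < 3:
            raise ValueError("need n >= 3 per pair")
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise ValueError(f"constant variable in pair ({xl}, {yl})")
        rho, p = sps.spearmanr(x, y)
        rho = float(rho)
        p = float(p)
        out.append(
            CorrelationResult(
                x_label=xl,
                y_label=yl,
                rho=rho,
                ci95=_fisher_ci(rho, n),
                p_raw=p,
                p_adjusted=bonferroni(p, m),
                n=n,
            )
        )
    return out


def kruskal_wallis_by(
    values: Sequence[float],
    groups: Sequence,
    m: int = 1,
    grouping: str = "group",
) -> GroupTestResult:
    """Kruskal-Wallis H test of ``values`` across ``groups`` labels.

    Tie-corrected H, chi-square p on k-1 degrees of freedom, Bonferroni
    family size m.  Requires at least two distinct groups.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(groups)
    if values.shape != labels.shape:
        raise ValueError("values and groups must align")
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need >= 2 groups for Kruskal-Wallis")
    samples = [values[labels == g] for g in uniq]
    if np.ptp(values) == 0:
        # all observations identical: every rank is tied, H = 0, p = 1
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*samples)
    return GroupTestResult(
        grouping=grouping,
        h_statistic=float(h),
        df=len(uniq) - 1,
        p_raw=float(p),
        p_adjusted=bonferroni(float(p), m),
    )


def _dummy_code(
    predictors: pd.DataFrame, reference_levels: Mapping[str, str] | None
) -> pd.DataFrame:
    reference_levels = dict(reference_levels or {})
    cols = []
    for name in predictors.columns:
        col = predictors[name]
        if pd.api.types.is_numeric_dtype(col) and name not in reference_levels:
            cols.append(col.astype(float))
            continue
        levels = list(pd.unique(col.astype(str)))
        ref = str(reference_levels.get(name, sorted(levels)[0]))
        if ref not in levels:
            raise ValueError(f"reference level {ref!r} absent from {name}")
        for lev in sorted(l for l in levels if l != ref):
            cols.append(
                pd.Series((col.astype(str) == lev).astype(float), name=f"{name}[{lev}]")
            )
    return pd.concat(cols, axis=1)


def _tolerances(design: pd.DataFrame) -> dict[str, float]:
    tol = {}
    x = design.to_numpy(dtype=float)
    for j, name in enumerate(design.columns):
        others = np.delete(x, j, axis=1)
        aux = sm.OLS(x[:, j], sm.add_constant(others)).fit()
        r2 = min(max(aux.rsquared, 0.0), 1.0)
        tol[name] = max(1.0 - r2, 0.0)
    return tol


def fit_linear_model(
    outcome: Sequence[float],
    predictors: pd.DataFrame,
    outcome_label: str = "y",
    reference_levels: Mapping[str, str] | None = None,
) -> RegressionResult:
    """OLS of ``outcome`` on ``predictors`` with dummy-coded categoricals.

    Categorical predictors are coded against the declared reference level
    (default: first level in sorted order).  The model F statistic tests
    all non-intercept terms jointly.  Per-predictor tolerance is reported
    and a warning logged below 0.1.
    """
    y = np.asarray(outcome, dtype=float)
    if len(y) != len(predictors):
        raise ValueError("outcome and predictors must align")
    design = _dummy_code(predictors, reference_levels)
    if len(y) <= design.shape[1] + 1:
        raise ValueError("need n > number of coefficients")
    if np.isnan(y).any() or design.isna().any().any():
        raise ValueError("missing values not allowed")
    tol = _tolerances(design) if design.shape[1] > 1 else {design.columns[0]: 1.0}
    for name, t in tol.items():
        if t < TOLERANCE_WARN:
            logger.warning("low tolerance (collinearity) for %s: %.4g", name, t)
    fit = sm.OLS(y, sm.add_constant(design.to_numpy(dtype=float))).fit()
    names = ["(intercept)", *design.columns]
    terms = tuple(
        RegressionTerm(
            term=nm,
            estimate=float(b),
            se=float(se),
            t_value=float(t),
            p_value=float(p),
        )
        for nm, b, se, t, p in zip(names, fit.params, fit.bse, fit.tvalues, fit.pvalues)
    )
    return RegressionResult(
        outcome=outcome_label,
        terms=terms,
        f_statistic=float(fit.fvalue),
        f_pvalue=float(fit.f_pvalue),
        r_squared=float(min(max(fit.rsquared, 0.0), 1.0)),
        n=len(y),
        tolerance=tol,
    )


def shapiro_report(values: Sequence[float], label: str = "x") -> dict:
    """Shapiro-Wilk normality screen: a reporting wrapper, not a gate."""
    w, p = sps.shapiro(np.asarray(values, dtype=float))
    return {"label": label, "W": float(w), "p": float(p), "n": len(values)}


def correlation_frame(results: Sequence[CorrelationResult]) -> pd.DataFrame:
    """Tidy one-row-per-test frame for CSV serialization."""
    return pd.DataFrame(
        {
            "x": [r.x_label for r in results],
            "y": [r.y_label for r in results],
            "rho": [r.rho for r in results],
            "ci_low": [r.ci95[0] for r in results],
            "ci_high": [r.ci95[1] for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_adjusted": [r.p_adjusted for r in results],
            "n": [r.n for r in results],
        }
    )


def regression_frame(result: RegressionResult) -> pd.DataFrame:
    """Tidy one-row-per-term frame mirroring a regression table."""
    rows = pd.DataFrame(
        {
            "outcome": result.outcome,
            "term": [t.term for t in result.terms],
            "estimate": [t.estimate for t in result.terms],
            "se": [t.se for t in result.terms],
            "t_value": [t.t_value for t in result.terms],
            "p_value": [t.p_value for t in result.terms],
        }
    )
    rows["f_statistic"] = result.f_statistic
    rows["f_pvalue"] = result.f_pvalue
    rows["r_squared"] = result.r_squared
    rows["n"] = result.n
    return rows
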