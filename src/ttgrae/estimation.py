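"""Estimate advancement rate A and criterion C from probit points.

Three estimators of increasing sophistication, all operating on the same
``ProbitPointSet``:

``endpoint_estimate``
    Difference the z-scores of the first and last interval at each
    attainment level, average, and rescale the observed midpoint span to a
    full year.  Simple, but ignores the interior intervals.
``per_level_regression``
    OLS of z on midpoint birthtime separately within each level; A is the
    unweighted mean of the slopes.
``stacked_regression``
    A single OLS over all points with birthtime plus level dummies
    (reference = the least severe level present).  The birthtime
    coefficient is A, the intercept is C, and the fit supplies R², the
    t-statistic and p-value for A.

``compare_models`` tests the model's two structural assumptions by nested
OLS ΔR² F-tests: adding a squared-birthtime term probes non-linearity
(e.g. seasonality would bend the line), adding birthtime × level
interactions probes whether advancement differs across severity levels.

OLS is unweighted by default, treating every probit point equally;
``weighted=True`` weights by approximate binomial information
n·φ(z)²/(p(1−p)), the usual grouped-probit weighting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from fractions import Fraction
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .tabulate_io import ProbitPointSet

__all__ = [
    "FitResult",
    "ModelComparison",
    "endpoint_estimate",
    "per_level_regression",
    "stacked_regression",
    "compare_models",
    "MONTHLY_SPAN_SCALE",
]

#: Whole-month convention for the endpoint method on 12 monthly intervals:
#: mid-September to mid-August is 11 of the year's 12 months.
MONTHLY_SPAN_SCALE = float(Fraction(12, 11))


@dataclass
class FitResult:
    """Result of one A-estimation method.

    ``A`` is the annual advancement (slope on birthtime), ``C`` the
    criterion for the reference (least severe) level, ``level_offsets`` the
    dummy coefficients of the other levels relative to it (stacked method
    only).  ``per_level`` carries the per-level slopes/differences behind
    the endpoint and per-level methods.
    """

    A: float
    C: Optional[float]
    method: str
    level_offsets: dict[str, float] = field(default_factory=dict)
    per_level: dict[str, float] = field(default_factory=dict)
    R2: Optional[float] = None
    t_A: Optional[float] = None
    df: Optional[int] = None
    p_A: Optional[float] = None
    n_points: int = 0
    warnings: list[str] = field(default_factory=list)

    def to_json(self, printed_decimals: int = 4) -> str:
        d = asdict(self)
        d["printed"] = {
            "A": round(self.A, printed_decimals),
            "C": None if self.C is None else round(self.C, printed_decimals),
            "R2": None if self.R2 is None else round(self.R2, printed_decimals),
            "t_A": None if self.t_A is None else round(self.t_A, 2),
        }
        return json.dumps(d, indent=2)


@dataclass
class ModelComparison:
    """ΔR² F-test of an augmented model against the stacked linear model."""

    F: float
    df1: int
    df2: int
    p: float
    variant: str
    R2_base: float
    R2_full: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def _level_order(points: ProbitPointSet) -> list[str]:
    return points.level_labels


def endpoint_estimate(
    points: ProbitPointSet, span_scale: Optional[float] = None
) -> FitResult:
    """First-versus-last-interval z difference, averaged over levels.

    Parameters
    ----------
    points : ProbitPointSet
    span_scale : float, optional
        Factor extrapolating the observed midpoint span to the full year.
        Defaults to ``1 / (t_last − t_first)``.  For twelve monthly
        midpoints the conventional whole-month ratio is
        :data:`MONTHLY_SPAN_SCALE` (12/11), which callers should pass
        explicitly when that convention is wanted.
    """
    t = points.t
    t_first, t_last = t.min(), t.max()
    if t_last <= t_first:
        raise ValueError("endpoint method needs at least two distinct birthtimes")
    if span_scale is None:
        span_scale = 1.0 / (t_last - t_first)
    diffs: dict[str, float] = {}
    warnings: list[str] = []
    for level in _level_order(points):
        sub = points.for_level(level)
        z_first = sub.loc[np.isclose(sub["t_B"], t_first), "z"]
        z_last = sub.loc[np.isclose(sub["t_B"], t_last), "z"]
        if z_first.empty or z_last.empty:
            warnings.append(f"level {level!r}: missing an endpoint interval; skipped")
            continue
        diffs[level] = float(z_last.iloc[0] - z_first.iloc[0])
    if not diffs:
        raise ValueError("no level has both endpoint intervals")
    a = float(np.mean(list(diffs.values()))) * span_scale
    # C: extrapolate the reference level's line back to t = 0
    ref = next(iter(diffs))
    sub = points.for_level(ref)
    z0 = float(sub.loc[np.isclose(sub["t_B"], t_first), "z"].iloc[0])
    c = z0 - a * t_first
    return FitResult(
        A=a, C=c, method="endpoint", per_level=diffs,
        n_points=2 * len(diffs), warnings=warnings,
    )


def _wls_weights(frame: pd.DataFrame) -> np.ndarray:
    p = frame["p"].to_numpy(float)
    n = frame["n"].to_numpy(float)
    z = frame["z"].to_numpy(float)
    return n * norm.pdf(z) ** 2 / (p * (1.0 - p))


def per_level_regression(points: ProbitPointSet, weighted: bool = False) -> FitResult:
    """OLS slope of z on birthtime within each level; A = mean of slopes."""
    slopes: dict[str, float] = {}
    intercepts: dict[str, float] = {}
    warnings: list[str] = []
    n_used = 0
    for level in _level_order(points):
        sub = points.for_level(level)
        if sub["t_B"].nunique() < 2:
            warnings.append(f"level {level!r}: fewer than 2 distinct birthtimes; skipped")
            continue
        X = sm.add_constant(sub["t_B"].to_numpy(float))
        y = sub["z"].to_numpy(float)
        if weighted:
            fit = sm.WLS(y, X, weights=_wls_weights(sub)).fit()
        else:
            fit = sm.OLS(y, X).fit()
        intercepts[level] = float(fit.params[0])
        slopes[level] = float(fit.params[1])
        n_used += len(sub)
    if not slopes:
        raise ValueError("no level has enough points for a regression")
    a = float(np.mean(list(slopes.values())))
    ref = next(iter(slopes))
    return FitResult(
        A=a, C=intercepts[ref], method="per_level", per_level=slopes,
        n_points=n_used, warnings=warnings,
    )


def _stacked_design(points: ProbitPointSet, variant: Optional[str] = None):
    """Design matrix: intercept, t_B, level dummies, plus optional terms."""
    frame = points.frame
    levels = _level_order(points)
    t = frame["t_B"].to_numpy(float)
    cols = [np.ones_like(t), t]
    names = ["const", "t_B"]
    for level in levels[1:]:  # reference = least severe level present
        cols.append((frame["level"] == level).to_numpy(float))
        names.append(f"D[{level}]")
    if variant == "quadratic":
        cols.append(t ** 2)
        names.append("t_B^2")
    elif variant == "interaction":
        for level in levels[1:]:
            cols.append(t * (frame["level"] == level).to_numpy(float))
            names.append(f"t_B:D[{level}]")
    elif variant is not None:
        raise ValueError(f"unknown model variant {variant!r}")
    X = np.column_stack(cols)
    return X, names, frame["z"].to_numpy(float)


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name a column that adds no rank, scanning left to right
        for j in range(1, X.shape[1] + 1):
            if np.linalg.matrix_rank(X[:, :j]) < j:
                raise ValueError(
                    f"design matrix is rank deficient: column {names[j - 1]!r} "
                    "is collinear with the preceding columns"
                )


def stacked_regression(points: ProbitPointSet, weighted: bool = False) -> FitResult:
    """Single OLS of all z on birthtime plus attainment-level dummies."""
    X, names, y = _stacked_design(points)
    _check_rank(X, names)
    if weighted:
        fit = sm.WLS(y, X, weights=_wls_weights(points.frame)).fit()
    else:
        fit = sm.OLS(y, X).fit()
    params = dict(zip(names, fit.params))
    offsets = {
        name[2:-1]: float(val) for name, val in params.items() if name.startswith("D[")
    }
    i_t = names.index("t_B")
    return FitResult(
        A=float(params["t_B"]),
        C=float(params["const"]),
        method="stacked",
        level_offsets=offsets,
        R2=float(fit.rsquared),
        t_A=float(fit.tvalues[i_t]),
        df=int(fit.df_resid),
        p_A=float(fit.pvalues[i_t]),
        n_points=len(y),
    )


def compare_models(points: ProbitPointSet, variant: str) -> ModelComparison:
    """ΔR² F-test of the quadratic or interaction augmentation.

    F = (ΔR² / q) / ((1 − R²_full) / df_full), with q the number of added
    terms and df_full the residual degrees of freedom of the larger model.
    When the base model already fits perfectly (ΔR² = 0 and residual
    variance 0) the statistic is reported as 0.
    """
    Xb, nb, y = _stacked_design(points)
    Xf, nf, _ = _stacked_design(points, variant=variant)
    _check_rank(Xf, nf)
    q = Xf.shape[1] - Xb.shape[1]
    df_full = len(y) - Xf.shape[1]
    if df_full <= 0:
        raise ValueError(
            f"no residual degrees of freedom for the {variant} comparison "
            f"({len(y)} points, {Xf.shape[1]} parameters)"
        )
    r2_base = float(sm.OLS(y, Xb).fit().rsquared)
    fit_full = sm.OLS(y, Xf).fit()
    r2_full = float(fit_full.rsquared)
    delta = max(r2_full - r2_base, 0.0)
    denom = (1.0 - r2_full) / df_full
    if delta == 0.0:
        f_stat = 0.0
    elif denom == 0.0:
        f_stat = float("inf")
    else:
        f_stat = (delta / q) / denom
    from scipy.stats import f as f_dist

    p = float(f_dist.sf(f_stat, q, df_full)) if np.isfinite(f_stat) else 0.0
    return ModelComparison(
        F=float(f_stat), df1=q, df2=df_full, p=p, variant=variant,
        R2_base=r2_base, R2_full=r2_full,
    )
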