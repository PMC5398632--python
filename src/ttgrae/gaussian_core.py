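"""Forward model for threshold selection from a travelling Gaussian.

The model assumes a *quality* (talent, ability, attribute) that is normally
distributed with unit variance within any single birthday, and whose mean
advances linearly through the cohort year.  Writing ``t`` for birthtime on
[0, 1] (0 = oldest possible member of the cohort, 1 = youngest), a fixed
selection threshold sits ``C + A·t`` standard deviations above the mean
quality of children born at time ``t``: the Gaussian "travels" a distance
``A`` over the year, so the younger the child, the deeper into their upper
tail the threshold cuts.  ``A`` is the annual advancement rate (SD units
per cohort year) and
``C`` is the selection criterion, the z-distance of the threshold above the
*oldest* children's mean.

Selection probabilities are therefore upper tails of the standard normal,
and observed selection proportions back-translate to z-scores via the
upper-tail probit.  Everything in this module is a pure function of (A, C)
and birthtime.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = [
    "TTGParams",
    "probit_upper",
    "selection_probability",
    "infer_params_two_point",
    "odds_ratio",
]


@dataclass(frozen=True)
class TTGParams:
    """Parameters of the travelling-Gaussian selection model.

    Attributes
    ----------
    A : float
        Annual advancement rate: the number of standard deviations the
        quality's mean advances over one cohort year.  Positive for
        developing qualities; negative values model decline.
    C : float
        Selection criterion: z-distance of the selection threshold above
        the mean of the oldest children (those born at t = 0).  Larger C
        means more severe selection.
    """

    A: float
    C: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.A) and math.isfinite(self.C)):
            raise ValueError(f"TTGParams must be finite, got A={self.A}, C={self.C}")


def probit_upper(p):
    """Upper-tail probit: the z with standard-normal mass ``p`` above it.

    Parameters
    ----------
    p : float or array_like
        Proportion(s) strictly inside (0, 1).

    Returns
    -------
    float or ndarray
        z such that P(Z >= z) = p for Z ~ N(0, 1); strictly decreasing in p.

    Raises
    ------
    ValueError
        If any proportion lies outside the open interval (0, 1).  Callers
        holding grouped data must filter (or continuity-correct) degenerate
        cells before transforming; see :mod:`ttgrae.tabulate_io`.
    """
    arr = np.asarray(p, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0.0) or np.any(arr >= 1.0):
        bad = arr[~(np.isfinite(arr) & (arr > 0.0) & (arr < 1.0))]
        raise ValueError(
            f"probit_upper requires proportions in (0, 1); got {bad.tolist()}"
        )
    z = norm.isf(arr)
    return float(z) if np.isscalar(p) or arr.ndim == 0 else z


def selection_probability(params: TTGParams, t):
    """Probability that a child born at birthtime ``t`` exceeds the threshold.

    Equals ``1 - Φ(C + A·t)``: the threshold sits ``C + A·t`` SDs above the
    mean quality of children born at ``t``.  Strictly decreasing in ``t``
    when ``A > 0`` — the younger the child, the further the threshold sits
    into their distribution's tail.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(~np.isfinite(t_arr)):
        raise ValueError("birthtime must be finite")
    p = norm.sf(params.C + params.A * t_arr)
    return float(p) if np.isscalar(t) or t_arr.ndim == 0 else p


def infer_params_two_point(
    p_old: float,
    p_young: float,
    t_old: float = 0.0,
    t_young: float = 1.0,
) -> TTGParams:
    """Back-translate two selection proportions into (A, C).

    The two observed upper-tail proportions pin down the threshold's
    z-distance at two birthtimes; the line through those (t, z) points has
    slope A, and its intercept at t = 0 is C.

    Parameters
    ----------
    p_old, p_young : float
        Selection proportions in (0, 1) for the older and younger group.
    t_old, t_young : float
        Birthtimes of the two groups, ``t_old < t_young``.  Defaults 0 and 1
        (oldest and youngest possible).

    Examples
    --------
    >>> infer_params_two_point(0.3085, 0.0968)  # doctest: +ELLIPSIS
    TTGParams(A=0.79..., C=0.50...)
    """
    if not (t_old < t_young):
        raise ValueError(
            f"degenerate birthtimes: need t_old < t_young, got {t_old} >= {t_young}"
        )
    z_old = probit_upper(p_old)
    z_young = probit_upper(p_young)
    a = (z_young - z_old) / (t_young - t_old)
    c = z_old - a * t_old  # extrapolate the line back to t = 0
    return TTGParams(A=a, C=c)


def odds_ratio(params: TTGParams, t1, t2) -> float:
    """Ratio of selection probabilities at two birthtimes, p(t1) / p(t2).

    For A > 0 and t1 < t2 this exceeds 1: the older child is that many
    times more likely to be selected.  Well defined for all finite inputs
    because normal upper tails are strictly positive.
    """
    return selection_probability(params, t1) / selection_probability(params, t2)
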