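"""Derived RAE statistics: discrimination, wastage, mean selected birthtime.

Once (A, C) are known, the selection curve over the cohort year is
``p(t) = 1 − Φ(C + A·t)``.  Three summaries matter to practitioners:

* the **discrimination index** I_D = p(0)/p(1), how many times more likely
  the oldest-possible child is to be selected than the youngest-possible;
* **wastage** W, the fraction of the potential talent intake lost to the
  age gradient.  Taking the no-RAE baseline as the horizontal at p(0),
  the selected fraction actually achieved is
  Grey = ∫₀¹ p(t) dt / p(0), and W = 1 − Grey.  The implied population
  expansion factor needed to offset the loss is PopEx = 1/(1 − W), and its
  reciprocal PopCon = 1 − W is the effective pool contraction;
* the **mean selected birthtime**, E[t | selected] under uniform births —
  the model's version of the descriptive "index of birthdays", which
  confounds A and C (it falls when either rises).

The wastage integral has a closed form via ∫ Φ(a + bt) dt =
[(a + bt)·Φ(a + bt) + φ(a + bt)] / b; an adaptive-quadrature route is kept
alongside as an independent cross-check.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

from scipy.integrate import quad
from scipy.stats import norm

from .gaussian_core import TTGParams, selection_probability

__all__ = [
    "RAEMetrics",
    "discrimination_index",
    "wastage",
    "mean_selected_birthtime",
]

_A_ZERO = 1e-12  # below this, treat the selection curve as flat


@dataclass(frozen=True)
class RAEMetrics:
    """Summary statistics of the fitted selection curve over one cohort."""

    A: float
    C: float
    p_oldest: float
    p_youngest: float
    I_D: float
    W: float
    PopEx: float
    PopCon: float
    t_bar_selected: float

    def to_json(self) -> str:
        d = asdict(self)
        d["printed"] = {
            "p_oldest_pct": round(100 * self.p_oldest, 4),
            "p_youngest_pct": round(100 * self.p_youngest, 4),
            "I_D": round(self.I_D, 2),
            "W": round(self.W, 3),
            "PopEx": round(self.PopEx, 2),
            "PopCon": round(self.PopCon, 2),
            "t_bar_selected": round(self.t_bar_selected, 4),
        }
        return json.dumps(d, indent=2)


def discrimination_index(params: TTGParams) -> float:
    """I_D = p(oldest possible) / p(youngest possible) = (1−Φ(C))/(1−Φ(C+A)).

    Evaluated at exactly t = 0 and t = 1 — the fitted line's extrapolation
    beyond the outermost interval midpoints, which is why it exceeds naive
    first-versus-last-interval ratios.
    """
    return selection_probability(params, 0.0) / selection_probability(params, 1.0)


def _phi_integral(a: float, b: float) -> float:
    """∫₀¹ Φ(a + b·t) dt via the identity ∫Φ(x)dx = x·Φ(x) + φ(x)."""
    g = lambda x: x * norm.cdf(x) + norm.pdf(x)
    return (g(a + b) - g(a)) / b


def wastage(params: TTGParams, method: str = "closed_form") -> RAEMetrics:
    """Wastage and its companions for the standard (A > 0) geometry.

    Parameters
    ----------
    params : TTGParams
        Requires A >= 0.  A = 0 gives W = 0 by convention (a flat selection
        curve wastes nothing).  For declining qualities (A < 0) reverse the
        time axis first, so that "oldest" again means most advantaged.
    method : {"closed_form", "quadrature"}
        Closed form uses the Gaussian integral identity; quadrature uses
        adaptive integration to 1e-10.  They agree to ~1e-10 and the
        quadrature route exists as an independent check.
    """
    if method not in ("closed_form", "quadrature"):
        raise ValueError(f"unknown wastage method {method!r}")
    a, c = params.A, params.C
    if a < 0:
        raise ValueError(
            "wastage assumes A >= 0; for a declining quality reverse the "
            "time axis (t -> 1 - t) so the advantaged end is t = 0"
        )
    p0 = selection_probability(params, 0.0)
    p1 = selection_probability(params, 1.0)
    if a < _A_ZERO:
        grey = 1.0
    elif method == "closed_form":
        # ∫₀¹ (1 − Φ(c + a·t)) dt, normalised by the baseline p(0)
        grey = (1.0 - _phi_integral(c, a)) / p0
    else:
        integral, _ = quad(
            lambda t: selection_probability(params, t), 0.0, 1.0,
            epsabs=1e-12, epsrel=1e-12,
        )
        grey = integral / p0
    w = 1.0 - grey
    return RAEMetrics(
        A=a,
        C=c,
        p_oldest=p0,
        p_youngest=p1,
        I_D=p0 / p1,
        W=w,
        PopEx=1.0 / grey,
        PopCon=grey,
        t_bar_selected=mean_selected_birthtime(params),
    )


def mean_selected_birthtime(params: TTGParams) -> float:
    """E[t_B | selected] under uniform births: ∫t·p(t)dt / ∫p(t)dt.

    Equals 0.5 when A = 0 and decreases as either A or C grows — the
    reason the raw mean birthtime of a selected group cannot separate the
    advancement rate from the selection severity.
    """
    if abs(params.A) < _A_ZERO:
        return 0.5
    num, _ = quad(
        lambda t: t * selection_probability(params, t), 0.0, 1.0,
        epsabs=1e-12, epsrel=1e-12,
    )
    den, _ = quad(
        lambda t: selection_probability(params, t), 0.0, 1.0,
        epsabs=1e-12, epsrel=1e-12,
    )
    return num / den
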