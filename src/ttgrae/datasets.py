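"""Bundled worked-example data.

Two small published summaries ship with the package so the full pipeline
can be exercised without external files:

* monthly teacher ratings of speaking & listening (five-point scale, "well
  below average" … "well above average") for children born September 2000
  – August 2001, from the UK Millennium Cohort Study's fourth sweep; and
* the English Premier League academy intake summary for the 2008–09
  competition year: 57% / 29% / 14% of an estimated 320 academy places go
  to boys born in the first / middle / last third of the year, against
  estimated tercile population pools of 33,736 / 32,378 / 33,886
  soccer-playing boys.

Both are tiny frequency summaries reproduced here as code; loaders return
the package's own container types.
"""

from __future__ import annotations

import numpy as np

from .cohort_calendar import BirthIntervalGrid, month_grid, tercile_grid
from .tabulate_io import ProbitPointSet, RatingTable, selection_points

__all__ = [
    "speaking_listening_ratings",
    "academy_pools",
    "academy_shares",
    "academy_total",
    "academy_selection_points",
]

_SPEAKING_LISTENING = {
    #        1   2    3    4   5   (well below ... well above average)
    "Sep": (3, 39, 161, 195, 72),
    "Oct": (13, 34, 169, 171, 61),
    "Nov": (6, 36, 197, 168, 66),
    "Dec": (9, 52, 206, 158, 44),
    "Jan": (9, 60, 168, 168, 50),
    "Feb": (13, 53, 183, 142, 36),
    "Mar": (11, 52, 195, 140, 40),
    "Apr": (12, 49, 186, 140, 31),
    "May": (17, 59, 209, 121, 30),
    "Jun": (22, 60, 213, 115, 25),
    "Jul": (22, 71, 171, 105, 33),
    "Aug": (13, 64, 211, 79, 24),
}

_LEVELS = ("1", "2", "3", "4", "5")

academy_shares = (0.57, 0.29, 0.14)
academy_total = 320
_ACADEMY_POOLS = (33736.0, 32378.0, 33886.0)


def speaking_listening_ratings() -> RatingTable:
    """Monthly five-level speaking & listening ratings as a RatingTable.

    The grid is the English school year (1 September start, 365-day
    convention); denominators are the monthly row totals, as the ratings
    cover every sampled child.
    """
    grid = month_grid("Sep", 365)
    counts = np.array([_SPEAKING_LISTENING[m] for m in grid.labels], dtype=float)
    return RatingTable(grid=grid, levels=_LEVELS, counts=counts)


def academy_pools(total: float = 100_000.0) -> BirthIntervalGrid:
    """Tercile grid with the academy study's population pools.

    The printed pools correspond to a 100,000-strong annual soccer-playing
    population; other ``total`` values scale them proportionally (the
    sensitivity analysis of the original study uses 50,000 and 150,000).
    """
    scale = total / 100_000.0
    return tercile_grid([p * scale for p in _ACADEMY_POOLS])


def academy_selection_points(total_pool: float = 100_000.0) -> ProbitPointSet:
    """Tercile probit points for the academy intake against the pools."""
    return selection_points(
        academy_pools(total_pool),
        shares=academy_shares,
        total_selected=academy_total,
    )
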