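"""Calendar grids: map birth intervals to midpoint birthtimes on [0, 1].

A cohort year (school year, competition year) is partitioned into labelled,
contiguous intervals — months, terciles, quarters, or arbitrary day ranges.
Each interval gets a midpoint birthtime ``t_mid = (days_before +
days_in/2) / year_length``, the usual grouped-data convention that the mean
birthtime within an interval is its midpoint.  Intervals optionally carry a
population pool size (the denominator for selection probabilities).

Two year-length conventions are supported: a plain 365-day year with
February = 28 days, and a 365.25-day year in which 29 February is weighted
by 0.25 (fractional day lengths are allowed for exactly this reason).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "BirthInterval",
    "BirthIntervalGrid",
    "month_grid",
    "tercile_grid",
    "custom_grid",
    "MONTH_LENGTHS",
    "MONTH_NAMES",
]

MONTH_NAMES = (
    "Jan", "Feb", "Mar", "Apr", "May", "Jun",
    "Jul", "Aug", "Sep", "Oct", "Nov", "Dec",
)

#: Non-leap month lengths; Feb is adjusted when year_length = 365.25.
MONTH_LENGTHS = {
    "Jan": 31, "Feb": 28, "Mar": 31, "Apr": 30, "May": 31, "Jun": 30,
    "Jul": 31, "Aug": 31, "Sep": 30, "Oct": 31, "Nov": 30, "Dec": 31,
}


@dataclass(frozen=True)
class BirthInterval:
    """One interval of the cohort year.

    ``days_before`` is the cumulative number of days from the cohort start
    to the interval's start; ``days_in`` its length (fractional allowed);
    ``pool`` the optional population count of children born in it.
    """

    label: str
    days_before: float
    days_in: float
    pool: Optional[float] = None
    t_mid: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if self.days_in <= 0:
            raise ValueError(f"interval {self.label!r}: days_in must be > 0")
        if self.pool is not None and self.pool < 0:
            raise ValueError(f"interval {self.label!r}: pool must be >= 0")


@dataclass(frozen=True)
class BirthIntervalGrid:
    """Ordered, contiguous partition of the cohort year.

    Invariants checked at construction: intervals are ordered, contiguous
    (each starts where the previous ends), start at day 0, and their
    lengths sum to ``year_length``.  Midpoints are derived, strictly
    increasing, and lie in (0, 1).
    """

    intervals: tuple[BirthInterval, ...]
    year_length: float = 365.0
    cohort_start: str = "Sep 1"

    def __post_init__(self) -> None:
        if not self.intervals:
            raise ValueError("grid needs at least one interval")
        if self.year_length <= 0:
            raise ValueError("year_length must be positive")
        expected_start = 0.0
        fixed = []
        for iv in self.intervals:
            if abs(iv.days_before - expected_start) > 1e-9:
                raise ValueError(
                    f"interval {iv.label!r} starts at day {iv.days_before}, "
                    f"expected {expected_start} (grid must be contiguous)"
                )
            t_mid = (iv.days_before + iv.days_in / 2.0) / self.year_length
            fixed.append(replace(iv, t_mid=t_mid))
            expected_start = iv.days_before + iv.days_in
        if abs(expected_start - self.year_length) > 1e-9:
            raise ValueError(
                f"interval lengths sum to {expected_start}, "
                f"not year_length = {self.year_length}"
            )
        object.__setattr__(self, "intervals", tuple(fixed))

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def labels(self) -> list[str]:
        return [iv.label for iv in self.intervals]

    @property
    def midpoints(self) -> np.ndarray:
        """Midpoint birthtimes t_B of every interval, in cohort order."""
        return np.array([iv.t_mid for iv in self.intervals])

    @property
    def pools(self) -> Optional[np.ndarray]:
        """Population pools, or None if any interval lacks one."""
        if any(iv.pool is None for iv in self.intervals):
            return None
        return np.array([iv.pool for iv in self.intervals], dtype=float)

    def with_pools(self, pools: Sequence[float]) -> "BirthIntervalGrid":
        if len(pools) != len(self.intervals):
            raise ValueError(
                f"got {len(pools)} pools for {len(self.intervals)} intervals"
            )
        ivs = tuple(
            replace(iv, pool=float(p)) for iv, p in zip(self.intervals, pools)
        )
        return BirthIntervalGrid(ivs, self.year_length, self.cohort_start)

    def reversed(self) -> "BirthIntervalGrid":
        """The same partition traversed youngest-first (t_mid -> 1 - t_mid)."""
        ivs = []
        start = 0.0
        for iv in reversed(self.intervals):
            ivs.append(replace(iv, days_before=start, t_mid=float("nan")))
            start += iv.days_in
        return BirthIntervalGrid(tuple(ivs), self.year_length, self.cohort_start)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "year_length": self.year_length,
            "cohort_start": self.cohort_start,
            "intervals": [
                {
                    "label": iv.label,
                    "days_before": iv.days_before,
                    "days_in": iv.days_in,
                    "pool": iv.pool,
                }
                for iv in self.intervals
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BirthIntervalGrid":
        ivs = tuple(
            BirthInterval(
                label=e["label"],
                days_before=float(e["days_before"]),
                days_in=float(e["days_in"]),
                pool=e.get("pool"),
            )
            for e in d["intervals"]
        )
        return cls(ivs, float(d["year_length"]), d.get("cohort_start", "Sep 1"))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, s: str) -> "BirthIntervalGrid":
        return cls.from_dict(json.loads(s))


def month_grid(
    start_month: str = "Sep",
    year_length: float = 365.0,
    pools: Optional[Sequence[float]] = None,
) -> BirthIntervalGrid:
    """Twelve monthly intervals beginning at ``start_month``.

    With the default 365-day year February counts 28 days; with a
    365.25-day year it counts 28.25 (29 February weighted by a quarter,
    its frequency in the Gregorian cycle).

    >>> g = month_grid("Sep")
    >>> round(g.intervals[2].t_mid, 4)   # November
    0.2082
    """
    start_month = start_month[:3].capitalize()
    if start_month not in MONTH_NAMES:
        raise ValueError(f"unknown month name: {start_month!r}")
    if year_length not in (365.0, 365.25, 365, float(365.25)):
        raise ValueError("year_length must be 365 or 365.25")
    feb = 28.0 if float(year_length) == 365.0 else 28.25
    i0 = MONTH_NAMES.index(start_month)
    order = [MONTH_NAMES[(i0 + k) % 12] for k in range(12)]
    ivs = []
    start = 0.0
    for name in order:
        length = feb if name == "Feb" else float(MONTH_LENGTHS[name])
        ivs.append(BirthInterval(label=name, days_before=start, days_in=length))
        start += length
    grid = BirthIntervalGrid(
        tuple(ivs), float(year_length), cohort_start=f"{start_month} 1"
    )
    if pools is not None:
        grid = grid.with_pools(pools)
    return grid


def tercile_grid(pools: Sequence[float]) -> BirthIntervalGrid:
    """Thirds of a September-start competition year, with population pools.

    The terciles Sep–Dec, Jan–Apr and May–Aug span 122, 120.25 and 123 days
    of a 365.25-day year (29 February, falling in the middle third, is
    weighted by 0.25), giving midpoints 0.1670, 0.4986 and 0.8316.
    """
    if len(pools) != 3:
        raise ValueError(f"tercile_grid needs exactly 3 pools, got {len(pools)}")
    lengths = (122.0, 120.25, 123.0)
    labels = ("T1", "T2", "T3")
    ivs = []
    start = 0.0
    for label, length, pool in zip(labels, lengths, pools):
        ivs.append(
            BirthInterval(
                label=label, days_before=start, days_in=length, pool=float(pool)
            )
        )
        start += length
    return BirthIntervalGrid(tuple(ivs), 365.25, cohort_start="Sep 1")


def custom_grid(
    lengths: Sequence[float],
    labels: Optional[Sequence[str]] = None,
    year_length: Optional[float] = None,
    pools: Optional[Sequence[float]] = None,
    cohort_start: str = "Sep 1",
) -> BirthIntervalGrid:
    """Arbitrary partition from a list of interval lengths in days.

    ``year_length`` defaults to the sum of the lengths, so quarters, halves
    and policy what-if splits need no dedicated constructor.
    """
    if labels is None:
        labels = [f"I{k + 1}" for k in range(len(lengths))]
    if len(labels) != len(lengths):
        raise ValueError("labels and lengths differ in number")
    if year_length is None:
        year_length = float(sum(lengths))
    ivs = []
    start = 0.0
    for label, length in zip(labels, lengths):
        ivs.append(BirthInterval(label=str(label), days_before=start, days_in=float(length)))
        start += float(length)
    grid = BirthIntervalGrid(tuple(ivs), year_length, cohort_start=cohort_start)
    if pools is not None:
        grid = grid.with_pools(pools)
    return grid
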