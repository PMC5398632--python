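"""Rating and selection tables, and their probit transformation.

The raw inputs of an RAE analysis come in two shapes:

* a frequency table of ordinal ratings by birth interval (e.g. teacher
  ratings 1–5 by birth month), and
* a selection summary: how many (or what share) of the selected group were
  born in each interval, against interval population pools.

Both reduce to the same regression-ready object: a set of probit points
``(t_B, level, p, z, n)`` where ``p`` is an upper-tail proportion — the
fraction of the interval's denominator at or above an attainment level, or
the fraction of the pool selected — and ``z = Φ⁻¹(1 − p)``.

Degenerate proportions (0 or 1) have no finite probit.  The default policy
excludes such points and records why; an optional continuity correction
``p* = (x + 0.5) / (n + 1)`` can be selected instead.  The lowest ordinal
level is everyone (p = 1 by construction) and is never transformed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort_calendar import BirthIntervalGrid
from .gaussian_core import probit_upper

__all__ = [
    "RatingTable",
    "ProbitPointSet",
    "ExcludedPoint",
    "cumulate",
    "to_probit_points",
    "selection_points",
    "read_rating_csv",
    "write_rating_csv",
    "read_points_csv",
    "write_points_csv",
    "load_config",
]

POINTS_COLUMNS = ["t_B", "level", "p", "z", "n"]


@dataclass(frozen=True)
class ExcludedPoint:
    interval: str
    level: str
    reason: str


@dataclass(frozen=True)
class RatingTable:
    """Counts of ordinal ratings per birth interval.

    ``levels`` are ordered lowest → highest; ``counts`` has one row per
    interval of ``grid`` and one column per level.  ``reverse_scored``
    marks items where a *high* raw rating denotes an undesirable quality
    (e.g. "constantly fidgets"); :meth:`reverse_coded` flips them so that
    positive advancement always means a positively valued quality.
    """

    grid: BirthIntervalGrid
    levels: tuple[str, ...]
    counts: np.ndarray
    reverse_scored: bool = False

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.shape != (len(self.grid), len(self.levels)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.grid)} intervals x {len(self.levels)} levels"
            )
        if np.any(counts < 0) or np.any(~np.isfinite(counts)):
            raise ValueError("counts must be finite and non-negative")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "levels", tuple(str(x) for x in self.levels))

    def reverse_coded(self) -> "RatingTable":
        """Flip the level order (an involution: applying twice is identity)."""
        return RatingTable(
            grid=self.grid,
            levels=tuple(reversed(self.levels)),
            counts=self.counts[:, ::-1].copy(),
            reverse_scored=not self.reverse_scored,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=list(self.levels))
        df.insert(0, "interval", self.grid.labels)
        pools = self.grid.pools
        if pools is not None:
            df["pool"] = pools
        return df


def cumulate(table: RatingTable) -> np.ndarray:
    """Upper-tail cumulative counts: entry (i, k) = Σ_{j >= k} counts(i, j).

    The column for the lowest level equals the row totals (everyone rated).
    """
    return table.counts[:, ::-1].cumsum(axis=1)[:, ::-1]


def _probit_or_exclude(
    x: float,
    n: float,
    zero_cell: str,
    interval: str,
    level: str,
    excluded: list[ExcludedPoint],
):
    """Return (p, z) for tail count x of n, or None if the point is dropped."""
    p = x / n
    if 0.0 < p < 1.0:
        return p, probit_upper(p)
    if zero_cell == "correct":
        p_star = (x + 0.5) / (n + 1.0)
        return p_star, probit_upper(p_star)
    excluded.append(
        ExcludedPoint(interval=interval, level=level, reason="degenerate proportion")
    )
    return None


@dataclass(frozen=True)
class ProbitPointSet:
    """Regression-ready probit points with a record of exclusions.

    ``frame`` has columns ``t_B`` (midpoint birthtime), ``level`` (label of
    the attainment level or selection criterion), ``p`` (upper-tail
    proportion in (0, 1)), ``z`` (its upper-tail probit) and ``n`` (the
    denominator behind p).
    """

    frame: pd.DataFrame
    excluded: tuple[ExcludedPoint, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        missing = [c for c in POINTS_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"probit point frame lacks columns {missing}")
        frame = self.frame[POINTS_COLUMNS].reset_index(drop=True)
        object.__setattr__(self, "frame", frame)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def t(self) -> np.ndarray:
        return self.frame["t_B"].to_numpy(dtype=float)

    @property
    def z(self) -> np.ndarray:
        return self.frame["z"].to_numpy(dtype=float)

    @property
    def level_labels(self) -> list[str]:
        """Distinct levels in severity order (order of first appearance)."""
        seen: list[str] = []
        for lv in self.frame["level"]:
            if lv not in seen:
                seen.append(lv)
        return seen

    def for_level(self, level: str) -> pd.DataFrame:
        return self.frame[self.frame["level"] == level]


def to_probit_points(
    table: RatingTable, zero_cell: str = "exclude"
) -> ProbitPointSet:
    """Transform a rating table into probit points, one per interval × level.

    For each interval, the upper-tail proportion at level k (k ≥ 2nd) is
    the cumulative count at-or-above k divided by the interval denominator
    — the pool size if the grid carries pools, otherwise the interval row
    total (ratings treated as exhaustive within the sampled children).

    Parameters
    ----------
    table : RatingTable
    zero_cell : {"exclude", "correct"}
        Policy for proportions of exactly 0 or 1: drop the point and record
        it, or apply the continuity correction (x + 0.5) / (n + 1).
    """
    if zero_cell not in ("exclude", "correct"):
        raise ValueError(f"unknown zero_cell policy {zero_cell!r}")
    cum = cumulate(table)
    pools = table.grid.pools
    mids = table.grid.midpoints
    excluded: list[ExcludedPoint] = []
    rows = []
    for i, label in enumerate(table.grid.labels):
        n = float(pools[i]) if pools is not None else float(cum[i, 0])
        if n <= 0:
            excluded.append(
                ExcludedPoint(interval=label, level="*", reason="zero row total")
            )
            continue
        for k in range(1, len(table.levels)):  # skip the ">= lowest" column
            level_label = f">= {table.levels[k]}"
            res = _probit_or_exclude(
                float(cum[i, k]), n, zero_cell, label, level_label, excluded
            )
            if res is None:
                continue
            p, z = res
            rows.append(
                {"t_B": mids[i], "level": level_label, "p": p, "z": z, "n": n}
            )
    frame = pd.DataFrame(rows, columns=POINTS_COLUMNS)
    # severity order = level order of the table, which interleaves by
    # interval above; re-sort by level rank then birthtime
    rank = {f">= {lv}": k for k, lv in enumerate(table.levels)}
    frame = frame.sort_values(
        by=["level", "t_B"], key=lambda s: s.map(rank) if s.name == "level" else s
    ).reset_index(drop=True)
    return ProbitPointSet(frame=frame, excluded=tuple(excluded))


def selection_points(
    grid: BirthIntervalGrid,
    selected: Optional[Sequence[float]] = None,
    shares: Optional[Sequence[float]] = None,
    total_selected: Optional[float] = None,
    zero_cell: str = "exclude",
    level: str = "selected",
) -> ProbitPointSet:
    """Probit points from per-interval selection counts against pools.

    Either absolute ``selected`` counts, or ``shares`` of a known
    ``total_selected``, may be given.  Shares × total may yield fractional
    counts; these are used as-is (they are expectations, not observations).

    >>> from ttgrae.cohort_calendar import tercile_grid
    >>> g = tercile_grid([33736, 32378, 33886])
    >>> pts = selection_points(g, shares=[0.57, 0.29, 0.14], total_selected=320)
    >>> [round(z, 3) for z in pts.z]
    [2.549, 2.763, 3.006]
    """
    pools = grid.pools
    if pools is None or np.any(pools <= 0):
        raise ValueError("selection_points requires positive pools on every interval")
    if selected is None:
        if shares is None or total_selected is None:
            raise ValueError("give either selected counts, or shares plus total_selected")
        selected = np.asarray(shares, dtype=float) * float(total_selected)
    else:
        selected = np.asarray(selected, dtype=float)
    if len(selected) != len(grid):
        raise ValueError(
            f"{len(selected)} selected counts for {len(grid)} intervals"
        )
    if np.any(selected < 0):
        raise ValueError("selected counts must be non-negative")
    over = selected > pools
    if np.any(over):
        bad = [grid.labels[i] for i in np.nonzero(over)[0]]
        raise ValueError(f"selected exceeds pool in interval(s) {bad}")
    mids = grid.midpoints
    excluded: list[ExcludedPoint] = []
    rows = []
    for i, label in enumerate(grid.labels):
        res = _probit_or_exclude(
            float(selected[i]), float(pools[i]), zero_cell, label, level, excluded
        )
        if res is None:
            continue
        p, z = res
        rows.append(
            {"t_B": mids[i], "level": level, "p": p, "z": z, "n": float(pools[i])}
        )
    frame = pd.DataFrame(rows, columns=POINTS_COLUMNS)
    return ProbitPointSet(frame=frame, excluded=tuple(excluded))


# ---------------------------------------------------------------------------
# CSV / config round-trips
# ---------------------------------------------------------------------------

def write_rating_csv(table: RatingTable, path_or_buf, provenance: Optional[dict] = None) -> None:
    """Write ``interval,<level1>,...,<levelK>[,pool]`` rows in cohort order."""
    df = table.to_frame()
    header = ""
    if provenance:
        header = "# " + json.dumps(provenance, sort_keys=True) + "\n"
    csv_text = header + df.to_csv(index=False)
    if hasattr(path_or_buf, "write"):
        path_or_buf.write(csv_text)
    else:
        with open(path_or_buf, "w", encoding="utf-8") as fh:
            fh.write(csv_text)


def read_rating_csv(
    path_or_buf,
    grid: Optional[BirthIntervalGrid] = None,
    year_length: float = 365.0,
    cohort_start: str = "Sep",
    reverse_scored: bool = False,
) -> RatingTable:
    """Read the rating-table CSV schema back into a :class:`RatingTable`.

    If no explicit grid is given, a monthly grid starting at
    ``cohort_start`` is assumed and the CSV's interval labels must match
    its twelve month names.
    """
    from .cohort_calendar import month_grid

    df = pd.read_csv(path_or_buf, comment="#")
    if df.columns[0] != "interval":
        raise ValueError(
            f"rating CSV must start with an 'interval' column, got {df.columns[0]!r}"
        )
    level_cols = [c for c in df.columns[1:] if c != "pool"]
    if grid is None:
        grid = month_grid(cohort_start, year_length)
    if list(df["interval"]) != grid.labels:
        raise ValueError(
            f"interval labels {list(df['interval'])} do not match grid {grid.labels}"
        )
    if "pool" in df.columns:
        grid = grid.with_pools(df["pool"].to_numpy(dtype=float))
    counts = df[level_cols].to_numpy(dtype=float)
    if np.any(counts < 0):
        bad = df["interval"][np.any(counts < 0, axis=1)].tolist()
        raise ValueError(f"negative counts in interval(s) {bad}")
    return RatingTable(
        grid=grid, levels=tuple(level_cols), counts=counts,
        reverse_scored=reverse_scored,
    )


def write_points_csv(points: ProbitPointSet, path_or_buf, provenance: Optional[dict] = None) -> None:
    """Write the regression-ready ``t_B,level,p,z,n`` schema."""
    header = ""
    if provenance:
        header = "# " + json.dumps(provenance, sort_keys=True) + "\n"
    csv_text = header + points.frame.to_csv(index=False)
    if hasattr(path_or_buf, "write"):
        path_or_buf.write(csv_text)
    else:
        with open(path_or_buf, "w", encoding="utf-8") as fh:
            fh.write(csv_text)


def read_points_csv(path_or_buf) -> ProbitPointSet:
    df = pd.read_csv(path_or_buf, comment="#")
    df["level"] = df["level"].astype(str)
    return ProbitPointSet(frame=df)


def load_config(path) -> dict:
    """Load a JSON or YAML analysis config.

    Recognised keys: ``year_length``, ``cohort_start``, ``levels``,
    ``reverse_scored``, ``zero_cell_policy``, ``pools`` or ``pool_total``
    plus ``pool_shares``.
    """
    text = open(path, encoding="utf-8").read()
    if str(path).endswith((".yaml", ".yml")):
        import yaml

        return yaml.safe_load(text)
    return json.loads(text)
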