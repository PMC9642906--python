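"""Semiannual calendar grids and binary behaviour trajectories.

Longitudinal questionnaire flags are mapped onto a fixed calendar grid of
half-year bins (calendar time, not patient time, so that all participants'
trajectories are aligned on the same axis and historical shifts in behaviour
are visible as column effects). Each cell of the resulting trajectory matrix
is 0, 1 or missing (NaN): the participant's behaviour state in that half-year,
or no information.

The module also computes the simple per-participant summaries (last value,
last two values, ever, mean) used as comparator predictors downstream.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TimeGrid",
    "TrajectoryMatrix",
    "TrajectorySummaries",
    "bin_to_semiannual",
    "summarize_trajectory",
    "summarize_matrix",
]


@dataclass(frozen=True)
class TimeGrid:
    """Contiguous half-year calendar bins.

    Bin ``i`` covers ``[bin_start(i), bin_end(i))``; H1 runs Jan 1 - Jul 1,
    H2 runs Jul 1 - Jan 1 of the next year. Bins are half-open so a visit
    on a boundary day belongs to the later bin.
    """

    start_year: int
    start_half: int  # 1 or 2
    n_bins: int

    def __post_init__(self) -> None:
        if self.start_half not in (1, 2):
            raise ValueError("start_half must be 1 or 2")
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")

    @classmethod
    def default(cls) -> "TimeGrid":
        """2001-H2 through 2017-H1 inclusive: 32 semiannual bins."""
        return cls(start_year=2001, start_half=2, n_bins=32)

    def _half_index(self, i: int) -> tuple[int, int]:
        h = self.start_year * 2 + (self.start_half - 1) + i
        return h // 2, h % 2 + 1

    def bin_start(self, i: int) -> dt.date:
        year, half = self._half_index(i)
        return dt.date(year, 1 if half == 1 else 7, 1)

    def bin_end(self, i: int) -> dt.date:
        year, half = self._half_index(i)
        return dt.date(year + 1, 1, 1) if half == 2 else dt.date(year, 7, 1)

    @property
    def span(self) -> tuple[dt.date, dt.date]:
        return self.bin_start(0), self.bin_end(self.n_bins - 1)

    def bin_of(self, date: dt.date) -> int | None:
        """Bin index containing ``date``, or None if outside the grid."""
        if isinstance(date, (pd.Timestamp, dt.datetime)):
            date = date.date() if hasattr(date, "date") else date
        start, end = self.span
        if not (start <= date < end):
            return None
        return (date.year * 2 + (0 if date.month <= 6 else 1)) - (
            self.start_year * 2 + self.start_half - 1
        )

    @property
    def labels(self) -> list[str]:
        return [f"{y}H{h}" for y, h in (self._half_index(i) for i in range(self.n_bins))]


@dataclass
class TrajectoryMatrix:
    """Participants x semiannual bins, entries in {0, 1, NaN}."""

    ids: np.ndarray  # participant identifiers, row order
    grid: TimeGrid
    values: np.ndarray  # float array, NaN = missing
    feature: str = "nsCAI"

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape != (len(self.ids), self.grid.n_bins):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.ids)} ids x {self.grid.n_bins} bins"
            )

    @property
    def n_participants(self) -> int:
        return len(self.ids)

    def row(self, participant_id) -> np.ndarray:
        idx = np.flatnonzero(self.ids == participant_id)
        if idx.size == 0:
            raise KeyError(participant_id)
        return self.values[idx[0]]

    def ever_positive(self) -> np.ndarray:
        """Boolean per row: any observed bin equals 1."""
        return np.nansum(self.values == 1, axis=1) > 0

    def mean_positivity(self) -> np.ndarray:
        """Per-row mean over non-missing bins (NaN for all-missing rows)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.values, axis=1)

    def subset(self, mask: np.ndarray) -> "TrajectoryMatrix":
        return TrajectoryMatrix(self.ids[mask], self.grid, self.values[mask], self.feature)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.ids, name="participant_id"),
                            columns=self.grid.labels)

    def to_csv(self, path) -> None:
        # missing bins serialise as empty cells; 0/1 as integers
        df = self.to_frame()
        out = df.map(lambda v: "" if np.isnan(v) else str(int(v)))
        out.to_csv(path)

    @classmethod
    def from_csv(cls, path, grid: TimeGrid | None = None,
                 feature: str = "nsCAI") -> "TrajectoryMatrix":
        df = pd.read_csv(path, index_col=0)
        if grid is None:
            y, h = int(df.columns[0][:4]), int(df.columns[0][-1])
            grid = TimeGrid(y, h, len(df.columns))
        return cls(df.index.to_numpy(), grid, df.to_numpy(dtype=float), feature)


def bin_to_semiannual(
    visits: pd.DataFrame,
    grid: TimeGrid,
    feature: str = "nsCAI",
    combine: str = "or",
) -> TrajectoryMatrix:
    """Aggregate dated behaviour flags onto the semiannual grid.

    Parameters
    ----------
    visits
        Long-format table with columns ``participant_id``, ``visit_date`` and
        a flag column named ``feature`` holding 0/1/NaN.
    combine
        ``"or"`` (default): a bin is 1 if any non-missing visit flag in that
        bin is 1. ``"last"``: the latest non-missing flag in the bin wins.

    Visits outside the grid span are dropped (the count is logged). A bin
    with no non-missing flag is missing (NaN).
    """
    if grid.n_bins < 1:
        raise ValueError("empty grid")
    if combine not in ("or", "last"):
        raise ValueError(f"unknown combine rule {combine!r}")
    required = {"participant_id", "visit_date", feature}
    missing_cols = required - set(visits.columns)
    if missing_cols:
        raise ValueError(f"visits table lacks columns: {sorted(missing_cols)}")

    v = visits.copy()
    v["visit_date"] = pd.to_datetime(v["visit_date"])
    v["_bin"] = [grid.bin_of(d.date()) for d in v["visit_date"]]
    n_dropped = int(v["_bin"].isna().sum())
    if n_dropped:
        logger.info("bin_to_semiannual: dropped %d visits outside grid span", n_dropped)
    v = v.dropna(subset=["_bin"])

    ids = np.array(sorted(visits["participant_id"].unique()))
    idx = {pid: i for i, pid in enumerate(ids)}
    values = np.full((len(ids), grid.n_bins), np.nan)

    obs = v.dropna(subset=[feature])
    if combine == "or":
        obs = obs.sort_values("visit_date")
        for (pid, b), grp in obs.groupby(["participant_id", "_bin"], sort=False):
            values[idx[pid], int(b)] = float(grp[feature].max())
    else:  # last-visit-wins
        obs = obs.sort_values("visit_date")
        for (pid, b), grp in obs.groupby(["participant_id", "_bin"], sort=False):
            values[idx[pid], int(b)] = float(grp[feature].iloc[-1])
    return TrajectoryMatrix(ids, grid, values, feature)


@dataclass(frozen=True)
class TrajectorySummaries:
    """Simple scalar summaries of one trajectory row (comparator predictors)."""

    last: int
    last_two: tuple[int, int]  # (older, newer) of the two latest observed values
    ever: int
    mean: float


def summarize_trajectory(row: Sequence[float]) -> TrajectorySummaries:
    """Summaries over the non-missing entries of a trajectory row.

    ``last`` is the latest observed value, ``last_two`` the two latest as
    (older, newer), ``ever`` the maximum, ``mean`` the arithmetic mean. With a
    single observed entry ``last_two`` repeats it. An all-missing row is an
    error (such participants fail the inclusion criteria upstream).
    """
    arr = np.asarray(row, dtype=float)
    obs = np.flatnonzero(~np.isnan(arr))
    if obs.size < 1:
        raise ValueError("trajectory row has no non-missing entries")
    vals = arr[obs].astype(int)
    last = int(vals[-1])
    older = int(vals[-2]) if vals.size >= 2 else last
    return TrajectorySummaries(
        last=last,
        last_two=(older, last),
        ever=int(vals.max()),
        mean=float(vals.mean()),
    )


def summarize_matrix(m: TrajectoryMatrix) -> pd.DataFrame:
    """Per-participant summary table (columns last, last_two_older,
    last_two_newer, ever, mean), indexed by participant id."""
    rows = []
    for i, pid in enumerate(m.ids):
        s = summarize_trajectory(m.values[i])
        rows.append((pid, s.last, s.last_two[0], s.last_two[1], s.ever, s.mean))
    return pd.DataFrame(
        rows, columns=["participant_id", "last", "last_two_older",
                       "last_two_newer", "ever", "mean"]
    ).set_index("participant_id")
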