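"""Domain containers and calendar/index arithmetic for daily visit series.

The package works on two views of the same data: a contiguous daily count
series (``DailySeries``) and its re-indexing as seven parallel weekly
sub-series, one per day of the week (``WeekdayPanel``).  All public indices
are 1-based: week ``t'`` runs 1..W and weekday ``tau`` runs 1..7, with
``tau = 1`` being the configured week start (Monday by default).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DailySeries",
    "WeekdayPanel",
    "ForecastRecord",
    "WEEKDAY_NAMES",
    "to_weekday_panel",
    "daily_index",
    "read_series",
    "write_series",
]

WEEKDAY_NAMES = (
    "monday",
    "tuesday",
    "wednesday",
    "thursday",
    "friday",
    "saturday",
    "sunday",
)


def _weekday_number(week_start: str | int) -> int:
    """Normalise a week-start spec to Python's weekday number (0=Monday)."""
    if isinstance(week_start, int):
        if not 0 <= week_start <= 6:
            raise ValueError(f"week_start out of range: {week_start}")
        return week_start
    try:
        return WEEKDAY_NAMES.index(week_start.strip().lower())
    except ValueError:
        raise ValueError(f"unknown week_start: {week_start!r}") from None


@dataclass
class DailySeries:
    """Contiguous dated daily visit counts.

    ``values[k]`` is the count for ``start_date + k`` days; there are no
    gaps.  Counts are non-negative; after preprocessing they may be
    non-integer (outlier replacement averages two neighbours).
    """

    start_date: dt.date
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if np.any(self.values < 0):
            raise ValueError("visit counts must be non-negative")

    def __len__(self) -> int:
        return len(self.values)

    def date_of(self, k: int) -> dt.date:
        """Calendar date of the 0-based position ``k``."""
        return self.start_date + dt.timedelta(days=k)

    def dates(self) -> list[dt.date]:
        return [self.date_of(k) for k in range(len(self))]


@dataclass
class WeekdayPanel:
    """A daily series arranged as a (weeks x 7) grid.

    Row ``t'-1`` holds week ``t'``; column ``tau-1`` holds weekday ``tau``.
    Construction requires whole weeks, so every cell is populated and the
    round trip with :class:`DailySeries` is lossless.
    """

    start_date: dt.date
    values: np.ndarray  # shape (weeks, 7)
    label: str = ""
    week_start: int = 0  # Python weekday number of tau=1 (0=Monday)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 7:
            raise ValueError("panel values must have shape (weeks, 7)")
        if self.values.shape[0] < 1:
            raise ValueError("panel needs at least one complete week")
        if self.start_date.weekday() != self.week_start:
            raise ValueError("panel start_date does not fall on the week start")

    @property
    def weeks(self) -> int:
        return self.values.shape[0]

    @property
    def weekday_of_first_day(self) -> int:
        """tau of the panel's first calendar day (always 1 by construction)."""
        return 1

    def cell(self, week: int, day: int) -> float:
        """Value of weekday ``day`` in week ``week`` (both 1-based)."""
        if not 1 <= week <= self.weeks:
            raise IndexError(f"week {week} outside 1..{self.weeks}")
        if not 1 <= day <= 7:
            raise IndexError(f"day {day} outside 1..7")
        return float(self.values[week - 1, day - 1])

    def weekday_series(self, day: int) -> np.ndarray:
        """The weekly sub-series of weekday ``day`` (1-based), length ``weeks``."""
        if not 1 <= day <= 7:
            raise IndexError(f"day {day} outside 1..7")
        return self.values[:, day - 1].copy()

    def to_daily_series(self) -> DailySeries:
        """Flatten in (t', tau) order back to a contiguous daily series."""
        return DailySeries(self.start_date, self.values.reshape(-1), self.label)

    def head(self, weeks: int) -> "WeekdayPanel":
        """The first ``weeks`` complete weeks as a new panel."""
        if not 1 <= weeks <= self.weeks:
            raise ValueError(f"weeks {weeks} outside 1..{self.weeks}")
        return WeekdayPanel(
            self.start_date, self.values[:weeks].copy(), self.label, self.week_start
        )


@dataclass
class ForecastRecord:
    """One forecast day: origin week, weekday, observed count and the three
    model predictions (seasonal-ARIMA arm, SES arm, combination)."""

    origin_week: int
    horizon_day: int
    observed: float
    pred_arima: float
    pred_ses: float
    pred_combined: float

    def __post_init__(self) -> None:
        if not 1 <= self.horizon_day <= 7:
            raise ValueError(f"horizon_day {self.horizon_day} outside 1..7")


def daily_index(week: int, day: int) -> int:
    """Position t of weekday ``day`` of week ``week`` in the daily series.

    t = 7*(week-1) + day, a 1-based bijection (1..W)x(1..7) -> 1..7W.
    """
    if week < 1:
        raise ValueError(f"week must be >= 1, got {week}")
    if not 1 <= day <= 7:
        raise ValueError(f"day must be in 1..7, got {day}")
    return 7 * (week - 1) + day


def to_weekday_panel(
    series: DailySeries, week_start: str | int = "monday"
) -> tuple[WeekdayPanel, int]:
    """Re-index a daily series as whole weeks, trimming partial weeks.

    Leading days before the first occurrence of ``week_start`` and trailing
    days that do not complete a week are dropped.  Returns the panel and the
    number of dropped days.
    """
    if len(series) == 0:
        raise ValueError("series is empty")
    ws = _weekday_number(week_start)
    lead = (ws - series.start_date.weekday()) % 7
    weeks = (len(series) - lead) // 7
    if weeks < 1:
        raise ValueError(
            f"series of length {len(series)} has no complete week starting on "
            f"{WEEKDAY_NAMES[ws]}"
        )
    body = series.values[lead : lead + 7 * weeks]
    dropped = len(series) - 7 * weeks
    panel = WeekdayPanel(
        series.start_date + dt.timedelta(days=lead),
        body.reshape(weeks, 7),
        series.label,
        ws,
    )
    return panel, dropped


def read_series(path, label: str = "") -> DailySeries:
    """Read a ``date,visits`` CSV into a :class:`DailySeries`.

    Dates must be ISO-8601 and strictly consecutive; visits must be
    non-negative.  A gap or duplicate raises with the offending date named.
    """
    frame = pd.read_csv(path)
    cols = [c.strip().lower() for c in frame.columns]
    if cols[:2] != ["date", "visits"]:
        raise ValueError(f"expected header 'date,visits', got {list(frame.columns)}")
    if len(frame) == 0:
        raise ValueError(f"no data rows in {path}")
    dates = pd.to_datetime(frame.iloc[:, 0], format="ISO8601").dt.date.to_numpy()
    for prev, cur in zip(dates, dates[1:]):
        delta = (cur - prev).days
        if delta == 0:
            raise ValueError(f"duplicate date {cur}")
        if delta != 1:
            raise ValueError(f"gap in dates after {prev} (next is {cur})")
    visits = pd.to_numeric(frame.iloc[:, 1]).to_numpy(dtype=float)
    bad = np.nonzero(visits < 0)[0]
    if bad.size:
        raise ValueError(f"negative count on {dates[bad[0]]}")
    return DailySeries(dates[0], visits, label)


def write_series(series: DailySeries, path) -> None:
    """Write a :class:`DailySeries` as a ``date,visits`` CSV (lossless)."""
    frame = pd.DataFrame(
        {"date": [d.isoformat() for d in series.dates()], "visits": series.values}
    )
    # integers stay integers on disk so read(write(s)) == s bit-exactly
    if np.allclose(series.values, np.round(series.values)):
        frame["visits"] = frame["visits"].astype(int)
    frame.to_csv(path, index=False)
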