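"""Holiday-outlier ("singularity") handling and train/test splitting.

National holidays depress outpatient volume far below the usual level of
that weekday.  Such days are detected purely statistically: within each
weekday's weekly sub-series, any value more than two sample standard
deviations from that weekday's mean is flagged, and replaced by the mean of
the same weekday in the adjacent weeks.  Detection and replacement are a
single pass; replacement always uses original (pre-replacement) neighbour
values, so the reported counts are stable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import WeekdayPanel

__all__ = [
    "SingularityEntry",
    "SingularityReport",
    "detect_singularities",
    "replace_singularities",
    "split_train_test",
    "preprocess_panel",
]


@dataclass(frozen=True)
class SingularityEntry:
    week: int
    day: int
    original: float
    replacement: float
    weekday_mean: float
    weekday_sd: float


@dataclass
class SingularityReport:
    entries: list[SingularityEntry]

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "week": e.week,
                    "day": e.day,
                    "original": e.original,
                    "replacement": e.replacement,
                    "mean": e.weekday_mean,
                    "sd": e.weekday_sd,
                }
                for e in self.entries
            ],
            columns=["week", "day", "original", "replacement", "mean", "sd"],
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def detect_singularities(panel: WeekdayPanel, n_sd: float = 2.0) -> SingularityReport:
    """Flag cells outside ``n_sd`` sample standard deviations of their
    weekday's mean.

    Statistics are computed per weekday over all weeks of the panel (sample
    SD, denominator n-1).  A zero-variance weekday flags nothing.  The
    replacement value recorded for each flagged cell is the mean of the same
    weekday in the previous and following weeks (single neighbour at the
    panel edges), always taken from original values.
    """
    if panel.weeks < 3:
        raise ValueError("singularity detection needs at least 3 weeks")
    x = panel.values
    entries: list[SingularityEntry] = []
    for day in range(1, 8):
        col = x[:, day - 1]
        mean = float(np.mean(col))
        sd = float(np.std(col, ddof=1))
        if sd == 0.0:
            continue
        for week in np.nonzero(np.abs(col - mean) > n_sd * sd)[0] + 1:
            neighbours = []
            if week > 1:
                neighbours.append(col[week - 2])
            if week < panel.weeks:
                neighbours.append(col[week])
            entries.append(
                SingularityEntry(
                    week=int(week),
                    day=int(day),
                    original=float(col[week - 1]),
                    replacement=float(np.mean(neighbours)),
                    weekday_mean=mean,
                    weekday_sd=sd,
                )
            )
    entries.sort(key=lambda e: (e.week, e.day))
    return SingularityReport(entries)


def replace_singularities(
    panel: WeekdayPanel, report: SingularityReport
) -> WeekdayPanel:
    """Apply a report's replacements, leaving every unflagged cell untouched."""
    values = panel.values.copy()
    for e in report.entries:
        values[e.week - 1, e.day - 1] = e.replacement
    return WeekdayPanel(panel.start_date, values, panel.label, panel.week_start)


def preprocess_panel(
    panel: WeekdayPanel, n_sd: float = 2.0
) -> tuple[WeekdayPanel, SingularityReport]:
    """Detect and replace singularities in one pass."""
    report = detect_singularities(panel, n_sd=n_sd)
    return replace_singularities(panel, report), report


def split_train_test(
    panel: WeekdayPanel, train_weeks: int
) -> tuple[WeekdayPanel, WeekdayPanel]:
    """Split a panel into the first ``train_weeks`` weeks and the remainder."""
    if not 1 <= train_weeks < panel.weeks:
        raise ValueError(
            f"train_weeks must be in 1..{panel.weeks - 1}, got {train_weeks}"
        )
    import datetime as dt

    train = panel.head(train_weeks)
    test = WeekdayPanel(
        panel.start_date + dt.timedelta(days=7 * train_weeks),
        panel.values[train_weeks:].copy(),
        panel.label,
        panel.week_start,
    )
    return train, test
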