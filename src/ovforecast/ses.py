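"""Single exponential smoothing on each day-of-week sub-series.

The daily series is split into seven weekly sub-series (all Mondays, all
Tuesdays, ...).  Each gets its own smoother

    level[t'+1] = alpha * x[t'] + (1 - alpha) * level[t'],

initialised with the mean of the first three weeks; level[W+1] is the
next-week prediction.  The smoothing constant is chosen on a grid by
minimum one-step mean squared error, scored from week 4 onward so the
initialisation window does not score itself; ties break by smaller MAPE,
then smaller alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import WeekdayPanel

__all__ = [
    "SesState",
    "default_alpha_grid",
    "ses_init",
    "ses_run",
    "ses_optimize_alpha",
    "ses_fit_panel",
    "ses_forecast_week",
]

SCORE_START_WEEK = 4  # first week t' whose one-step error enters the objective


def default_alpha_grid() -> np.ndarray:
    """0.01, 0.02, ..., 0.99."""
    return np.round(np.arange(1, 100) / 100.0, 2)


@dataclass
class SesState:
    """A fitted smoother for one weekday's weekly sub-series.

    ``smoothed[i]`` is the level for week ``i+1``; the array has length
    W + 1, its last entry being the prediction for the next, unobserved
    week.  ``one_step_errors`` are observed - smoothed for weeks
    t' >= 4.
    """

    tau: int
    alpha: float
    initial_level: float
    smoothed: np.ndarray
    one_step_errors: np.ndarray
    mse: float
    mape: float

    @property
    def prediction(self) -> float:
        """Level for week W+1, the one-week-ahead forecast."""
        return float(self.smoothed[-1])


def ses_init(weekday_series) -> float:
    """Initial level: mean of the first three weekly observations."""
    x = np.asarray(weekday_series, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 weeks to initialise the smoother")
    return float(np.mean(x[:3]))


def ses_run(weekday_series, alpha: float, tau: int = 0) -> SesState:
    """Run the smoothing recursion for a fixed alpha."""
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    x = np.asarray(weekday_series, dtype=float)
    init = ses_init(x)
    smoothed = np.empty(len(x) + 1)
    smoothed[0] = init
    for i in range(len(x)):
        smoothed[i + 1] = alpha * x[i] + (1.0 - alpha) * smoothed[i]
    start = SCORE_START_WEEK - 1
    errors = x[start:] - smoothed[start : len(x)]
    mse = float(np.mean(errors**2)) if len(errors) else np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(errors) / np.abs(x[start:])
    mape = float(np.mean(rel) * 100.0) if len(errors) else np.nan
    return SesState(
        tau=tau,
        alpha=float(alpha),
        initial_level=init,
        smoothed=smoothed,
        one_step_errors=errors,
        mse=mse,
        mape=mape,
    )


def ses_optimize_alpha(weekday_series, grid=None, tau: int = 0) -> SesState:
    """Grid-search the smoothing constant.

    Primary criterion: one-step MSE over weeks >= 4; ties break by MAPE,
    then by smaller alpha.
    """
    if grid is None:
        grid = default_alpha_grid()
    grid = np.asarray(grid, dtype=float)
    if len(grid) == 0:
        raise ValueError("alpha grid is empty")
    if np.any((grid <= 0) | (grid >= 1)):
        raise ValueError("alpha grid must lie strictly inside (0, 1)")
    best: SesState | None = None
    for alpha in grid:
        state = ses_run(weekday_series, alpha, tau=tau)
        if best is None or (state.mse, state.mape, state.alpha) < (
            best.mse,
            best.mape,
            best.alpha,
        ):
            best = state
    return best


def ses_fit_panel(panel: WeekdayPanel, grid=None) -> list[SesState]:
    """Optimise one smoother per weekday; returns the 7 fitted states."""
    if panel.weeks < SCORE_START_WEEK:
        raise ValueError(f"panel needs >= {SCORE_START_WEEK} weeks, has {panel.weeks}")
    return [
        ses_optimize_alpha(panel.weekday_series(tau), grid, tau=tau)
        for tau in range(1, 8)
    ]


def ses_forecast_week(panel: WeekdayPanel, grid=None) -> np.ndarray:
    """Next-week predictions for weekdays 1..7."""
    return np.array([s.prediction for s in ses_fit_panel(panel, grid)])


def states_to_frame(states: list[SesState]) -> pd.DataFrame:
    """Run-report rows: day, alpha, initial, mse, mape."""
    return pd.DataFrame(
        [
            {
                "day": s.tau,
                "alpha": s.alpha,
                "initial": s.initial_level,
                "mse": s.mse,
                "mape": s.mape,
            }
            for s in states
        ],
        columns=["day", "alpha", "initial", "mse", "mape"],
    )
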