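"""Inverse-error-energy forecast combination and the rolling driver.

For each weekday tau the two arms' training residuals give error energies
E_i = sqrt(sum e^2); the combination weight of arm i is

    l_i = E_i^-1 / (E_1^-1 + E_2^-1),

so the arm that fitted that weekday better dominates, and l_1 + l_2 = 1.
The rolling driver forecasts each test week from all data up to the week
before: the expanding training window is outlier-cleaned, both arms are
refitted (the ARMA lag sets frozen after the first origin, the smoothing
constants re-optimised), weights recomputed, and seven daily records
emitted against the untouched observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import DailySeries, ForecastRecord, WeekdayPanel, to_weekday_panel
from .preprocess import preprocess_panel
from .sarima import (
    DifferencingSpec,
    SubsetArmaModel,
    fit_subset_arma,
    forecast as sarima_forecast,
    difference,
    prune_insignificant,
    select_orders_bic,
)
from .ses import SesState, ses_fit_panel

__all__ = [
    "CombinationWeights",
    "RollingConfig",
    "RollingResult",
    "residual_energy",
    "combine_weights",
    "combined_forecast",
    "compute_weights_for_origin",
    "rolling_forecast",
    "records_to_frame",
]


@dataclass
class CombinationWeights:
    """Per-weekday energies and weights, index tau-1 for tau = 1..7."""

    E1: np.ndarray
    E2: np.ndarray
    l1: np.ndarray
    l2: np.ndarray

    def __post_init__(self) -> None:
        for name in ("E1", "E2", "l1", "l2"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (7,):
                raise ValueError(f"{name} must have 7 entries (one per weekday)")
            setattr(self, name, arr)

    def to_frame(self, origin_week: int | None = None) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "day": np.arange(1, 8),
                "E1": self.E1,
                "E2": self.E2,
                "l1": self.l1,
                "l2": self.l2,
            }
        )
        if origin_week is not None:
            frame.insert(0, "origin_week", origin_week)
        return frame


def residual_energy(residuals) -> float:
    """Root of the summed squared residuals, E = sqrt(sum e^2)."""
    e = np.asarray(residuals, dtype=float)
    if e.size == 0:
        raise ValueError("residuals are empty")
    return float(np.sqrt(e @ e))


def combine_weights(E1: float, E2: float) -> tuple[float, float]:
    """Inverse-energy weights; an exactly-zero energy takes all the weight."""
    if E1 < 0 or E2 < 0:
        raise ValueError("error energies must be non-negative")
    if E1 == 0.0 and E2 == 0.0:
        raise ValueError("both error energies are zero (degenerate perfect fits)")
    if E1 == 0.0:
        return 1.0, 0.0
    if E2 == 0.0:
        return 0.0, 1.0
    inv1, inv2 = 1.0 / E1, 1.0 / E2
    return inv1 / (inv1 + inv2), inv2 / (inv1 + inv2)


def combined_forecast(pred1, pred2, weights: CombinationWeights) -> np.ndarray:
    """Per-weekday convex combination l1*pred1 + l2*pred2."""
    p1 = np.asarray(pred1, dtype=float)
    p2 = np.asarray(pred2, dtype=float)
    if p1.shape != (7,) or p2.shape != (7,):
        raise ValueError("both arm predictions must have 7 entries")
    return weights.l1 * p1 + weights.l2 * p2


def compute_weights_for_origin(
    arm1_residuals_by_tau, arm2_residuals_by_tau
) -> CombinationWeights:
    """Weights from each arm's per-weekday training residuals.

    Inputs are sequences of 7 residual arrays (index tau-1).  If both arms
    fit a weekday perfectly (both energies zero) the weights fall back to an
    even split rather than failing — the combination is then indifferent.
    """
    if len(arm1_residuals_by_tau) != 7 or len(arm2_residuals_by_tau) != 7:
        raise ValueError("need residuals for all 7 weekdays from each arm")
    E1 = np.empty(7)
    E2 = np.empty(7)
    l1 = np.empty(7)
    l2 = np.empty(7)
    for i in range(7):
        E1[i] = residual_energy(arm1_residuals_by_tau[i])
        E2[i] = residual_energy(arm2_residuals_by_tau[i])
        if E1[i] == 0.0 and E2[i] == 0.0:
            l1[i] = l2[i] = 0.5
        else:
            l1[i], l2[i] = combine_weights(E1[i], E2[i])
    return CombinationWeights(E1, E2, l1, l2)


@dataclass
class RollingConfig:
    """Settings for the rolling one-week-ahead evaluation."""

    train_weeks: int
    test_weeks: int | None = None
    week_start: str | int = "monday"
    diff: DifferencingSpec = field(default_factory=DifferencingSpec)
    p_max: int = 3
    q_max: int = 7
    prune_t: float = 1.96
    alpha_grid: np.ndarray | None = None
    preprocess: bool = True
    n_sd: float = 2.0
    clip_zero: bool = False

    def __post_init__(self) -> None:
        if self.train_weeks < 4:
            raise ValueError("train_weeks must be >= 4 (SES needs 4 weeks)")
        if self.test_weeks is not None and self.test_weeks < 1:
            raise ValueError("test_weeks must be >= 1")
        if self.p_max < 0 or self.q_max < 0:
            raise ValueError("p_max and q_max must be non-negative")


@dataclass
class RollingResult:
    records: list[ForecastRecord]
    weights: list[tuple[int, CombinationWeights]]
    ar_lags: set[int]
    ma_lags: set[int]
    models: list[SubsetArmaModel] = field(default_factory=list)
    ses_states: list[list[SesState]] = field(default_factory=list)

    @property
    def origins(self) -> list[int]:
        return [w for w, _ in self.weights]

    def weights_frame(self) -> pd.DataFrame:
        return pd.concat(
            [w.to_frame(origin) for origin, w in self.weights], ignore_index=True
        )


def _sarima_residuals_by_tau(
    model: SubsetArmaModel, n_daily: int
) -> list[np.ndarray]:
    """Slice the daily residual sequence by weekday position (warm-up dropped).

    Daily position t (0-based, t=1 day one) has tau = t mod 7 + 1 because the
    training window starts on the week-start day.
    """
    eps = model.residuals_diff
    offset = model.diff.offset
    positions = np.arange(n_daily)
    out = []
    for tau in range(1, 8):
        idx = positions[(positions % 7) == (tau - 1)]
        idx = idx[idx >= offset]
        vals = eps[idx - offset]
        out.append(vals[np.isfinite(vals)])
    return out


def rolling_forecast(series: DailySeries, config: RollingConfig) -> RollingResult:
    """One-week-ahead rolling evaluation over the test weeks.

    Week-by-week protocol: preprocess the expanding training window, refit
    both arms, derive per-weekday weights from their training residuals, and
    forecast the next seven days; observed test values are never modified.
    """
    panel, _ = to_weekday_panel(series, config.week_start)
    if config.train_weeks >= panel.weeks:
        raise ValueError(
            f"train_weeks {config.train_weeks} leaves no test weeks "
            f"(panel has {panel.weeks})"
        )
    avail = panel.weeks - config.train_weeks
    test_weeks = avail if config.test_weeks is None else min(config.test_weeks, avail)

    records: list[ForecastRecord] = []
    weights_out: list[tuple[int, CombinationWeights]] = []
    models: list[SubsetArmaModel] = []
    states_out: list[list[SesState]] = []
    ar_lags: set[int] | None = None
    ma_lags: set[int] | None = None

    for i in range(test_weeks):
        origin = config.train_weeks + i
        train_panel = panel.head(origin)
        if config.preprocess:
            clean, _ = preprocess_panel(train_panel, n_sd=config.n_sd)
        else:
            clean = train_panel
        daily = clean.to_daily_series().values
        try:
            w = difference(daily, config.diff)
            if ar_lags is None:
                cand_ar, cand_ma = select_orders_bic(w, config.p_max, config.q_max)
                initial = fit_subset_arma(w, cand_ar, cand_ma, diff=config.diff)
                pruned = prune_insignificant(initial, w, config.prune_t)
                ar_lags = set(pruned.ar_terms)
                ma_lags = set(pruned.ma_terms)
                model = pruned
            else:
                model = fit_subset_arma(w, ar_lags, ma_lags, diff=config.diff)
            pred_arima = sarima_forecast(model, daily, 7)
            states = ses_fit_panel(clean, config.alpha_grid)
        except Exception as exc:
            raise RuntimeError(
                f"arm fitting failed at rolling origin week {origin}: {exc}"
            ) from exc
        pred_ses = np.array([s.prediction for s in states])
        weights = compute_weights_for_origin(
            _sarima_residuals_by_tau(model, len(daily)),
            [s.one_step_errors for s in states],
        )
        pred_comb = combined_forecast(pred_arima, pred_ses, weights)
        if config.clip_zero:
            pred_arima = np.maximum(pred_arima, 0.0)
            pred_ses = np.maximum(pred_ses, 0.0)
            pred_comb = np.maximum(pred_comb, 0.0)
        observed = panel.values[origin]  # week origin+1, untouched
        for tau in range(1, 8):
            records.append(
                ForecastRecord(
                    origin_week=origin,
                    horizon_day=tau,
                    observed=float(observed[tau - 1]),
                    pred_arima=float(pred_arima[tau - 1]),
                    pred_ses=float(pred_ses[tau - 1]),
                    pred_combined=float(pred_comb[tau - 1]),
                )
            )
        weights_out.append((origin, weights))
        models.append(model)
        states_out.append(states)

    return RollingResult(
        records=records,
        weights=weights_out,
        ar_lags=ar_lags or set(),
        ma_lags=ma_lags or set(),
        models=models,
        ses_states=states_out,
    )


def records_to_frame(records: list[ForecastRecord]) -> pd.DataFrame:
    """CSV layout: origin_week, day, observed, arima, ses, combined."""
    return pd.DataFrame(
        [
            {
                "origin_week": r.origin_week,
                "day": r.horizon_day,
                "observed": r.observed,
                "arima": r.pred_arima,
                "ses": r.pred_ses,
                "combined": r.pred_combined,
            }
            for r in records
        ],
        columns=["origin_week", "day", "observed", "arima", "ses", "combined"],
    )


def records_from_frame(frame: pd.DataFrame) -> list[ForecastRecord]:
    return [
        ForecastRecord(
            origin_week=int(row.origin_week),
            horizon_day=int(row.day),
            observed=float(row.observed),
            pred_arima=float(row.arima),
            pred_ses=float(row.ses),
            pred_combined=float(row.combined),
        )
        for row in frame.itertuples()
    ]
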