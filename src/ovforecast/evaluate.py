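"""Error metrics and comparison reports.

MAPE = mean of |observed - predicted| / observed x 100 over all days; the
report also splits workdays (Monday..Friday, tau 1..5) from weekends
(tau 6..7) and gives residual mean and sample SD per model.  A zero
observed count makes the percentage error undefined: the default policy is
to raise, and ``zero_policy="skip"`` drops such days explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ForecastRecord

__all__ = [
    "ape",
    "mape",
    "residual_moments",
    "ModelScores",
    "EvaluationReport",
    "build_report",
]

MODELS = ("arima", "ses", "combined")
WORKDAYS = (1, 2, 3, 4, 5)
WEEKENDS = (6, 7)


def ape(observed: float, predicted: float) -> float:
    """Absolute percentage error of one day, in percent."""
    if observed == 0:
        raise ZeroDivisionError("APE undefined for an observed count of zero")
    return abs(observed - predicted) / abs(observed) * 100.0


def _pair(observed, predicted):
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError(f"length mismatch: {obs.shape} vs {pred.shape}")
    if obs.size == 0:
        raise ValueError("empty sequences")
    return obs, pred


def mape(observed, predicted, zero_policy: str = "error") -> float:
    """Mean absolute percentage error over a sequence, in percent."""
    obs, pred = _pair(observed, predicted)
    if np.any(obs == 0):
        if zero_policy == "skip":
            keep = obs != 0
            obs, pred = obs[keep], pred[keep]
            if obs.size == 0:
                raise ValueError("all observed values are zero")
        else:
            raise ZeroDivisionError("MAPE undefined: observed contains zero")
    return float(np.mean(np.abs(obs - pred) / np.abs(obs)) * 100.0)


def residual_moments(observed, predicted) -> tuple[float, float]:
    """Mean and sample SD (n-1) of the residuals observed - predicted."""
    obs, pred = _pair(observed, predicted)
    if obs.size < 2:
        raise ValueError("need at least 2 residuals for a sample SD")
    res = obs - pred
    return float(np.mean(res)), float(np.std(res, ddof=1))


@dataclass
class ModelScores:
    overall_mape: float
    workdays_mape: float
    weekends_mape: float
    per_day_ape: dict[int, np.ndarray]  # tau -> APEs across origins
    residual_mean: float
    residual_sd: float


@dataclass
class EvaluationReport:
    """Per-model accuracy summary over a set of forecast records."""

    scores: dict[str, ModelScores]
    n_days: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for model in MODELS:
            s = self.scores[model]
            rows.append(
                {
                    "model": model,
                    "overall_mape": s.overall_mape,
                    "workdays_mape": s.workdays_mape,
                    "weekends_mape": s.weekends_mape,
                    "residual_mean": s.residual_mean,
                    "residual_sd": s.residual_sd,
                }
            )
        return pd.DataFrame(rows)

    def per_day_frame(self) -> pd.DataFrame:
        rows = []
        for model in MODELS:
            for tau, apes in self.scores[model].per_day_ape.items():
                for k, value in enumerate(apes):
                    rows.append({"model": model, "day": tau, "origin": k, "ape": value})
        return pd.DataFrame(rows, columns=["model", "day", "origin", "ape"])

    def summary(self) -> str:
        lines = [f"Evaluation over {self.n_days} forecast days"]
        header = f"{'model':<10}{'overall':>10}{'workdays':>10}{'weekends':>10}{'res mean':>10}{'res SD':>10}"
        lines.append(header)
        for model in MODELS:
            s = self.scores[model]
            lines.append(
                f"{model:<10}{s.overall_mape:>9.2f}%{s.workdays_mape:>9.2f}%"
                f"{s.weekends_mape:>9.2f}%{s.residual_mean:>10.4f}{s.residual_sd:>10.4f}"
            )
        return "\n".join(lines)


def build_report(
    records: list[ForecastRecord], zero_policy: str = "error"
) -> EvaluationReport:
    """Score the three models over whole-week forecast records."""
    if not records:
        raise ValueError("no forecast records to evaluate")
    if len(records) % 7 != 0:
        raise ValueError("records must cover whole weeks (multiple of 7 rows)")
    obs = np.array([r.observed for r in records])
    taus = np.array([r.horizon_day for r in records])
    preds = {
        "arima": np.array([r.pred_arima for r in records]),
        "ses": np.array([r.pred_ses for r in records]),
        "combined": np.array([r.pred_combined for r in records]),
    }
    scores = {}
    for model, pred in preds.items():
        work = np.isin(taus, WORKDAYS)
        per_day = {}
        for tau in range(1, 8):
            sel = taus == tau
            o, p = obs[sel], pred[sel]
            if zero_policy == "skip":
                keep = o != 0
                o, p = o[keep], p[keep]
            elif np.any(o == 0):
                raise ZeroDivisionError(
                    "MAPE undefined: observed contains zero (use zero_policy='skip')"
                )
            per_day[tau] = np.abs(o - p) / np.abs(o) * 100.0 if o.size else np.array([])
        mean, sd = residual_moments(obs, pred)
        scores[model] = ModelScores(
            overall_mape=mape(obs, pred, zero_policy),
            workdays_mape=mape(obs[work], pred[work], zero_policy),
            weekends_mape=mape(obs[~work], pred[~work], zero_policy),
            per_day_ape=per_day,
            residual_mean=mean,
            residual_sd=sd,
        )
    return EvaluationReport(scores=scores, n_days=len(records))
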