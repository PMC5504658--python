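"""Synthetic daily outpatient-demand generator and the published worked
example.

Real hospital visit series combine a strong day-of-week profile (weekend
troughs), mild annual seasonality, occasional holiday collapses and
autocorrelated day-to-day noise.  ``generate`` produces count series with
exactly those ingredients so every pipeline stage is testable without any
data download; ``worked_example_fixture`` packages the published week-45
observed/predicted rows for the endocrinology (EOV) and respiratory (ROV)
series, which anchor the exact-value tests.
"""

from __future__ import annotations

import datetime as dt
import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import yaml

from .core import DailySeries, WeekdayPanel

__all__ = [
    "ScenarioConfig",
    "generate",
    "generate_ses_truth",
    "worked_example_fixture",
    "load_preset",
    "PRESETS",
]

PRESETS = ("eov_like", "rov_like", "flat_control")

# First Monday of 2014, matching the study period's alignment.
DEFAULT_START = dt.date(2014, 1, 6)


@dataclass
class ScenarioConfig:
    """Parameters of the synthetic demand process."""

    weeks: int
    weekday_profile: tuple[float, ...]  # mean visits for tau = 1..7
    trend_per_week: float = 0.0
    annual_amplitude: float = 0.0
    ar_coefficient: float = 0.0
    noise_sd: float = 0.0
    holidays: tuple[tuple[int, int, float], ...] = ()  # (week, day, depression)
    seed: int = 0
    label: str = "synthetic"

    def __post_init__(self) -> None:
        if self.weeks < 5:
            raise ValueError(f"weeks must be >= 5, got {self.weeks}")
        profile = tuple(float(v) for v in self.weekday_profile)
        if len(profile) != 7:
            raise ValueError("weekday_profile needs exactly 7 values")
        if any(v <= 0 for v in profile):
            raise ValueError("weekday_profile values must be positive")
        self.weekday_profile = profile
        if self.annual_amplitude < 0:
            raise ValueError(f"annual_amplitude must be >= 0, got {self.annual_amplitude}")
        if not -1.0 < self.ar_coefficient < 1.0:
            raise ValueError(f"ar_coefficient must be in (-1, 1), got {self.ar_coefficient}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        holidays = tuple(
            (int(w), int(d), float(f)) for w, d, f in self.holidays
        )
        for w, d, f in holidays:
            if not 1 <= w <= self.weeks:
                raise ValueError(f"holidays: week {w} outside 1..{self.weeks}")
            if not 1 <= d <= 7:
                raise ValueError(f"holidays: day {d} outside 1..7")
            if not 0.0 <= f < 1.0:
                raise ValueError(f"holidays: depression factor {f} outside [0, 1)")
        self.holidays = holidays


def generate(config: ScenarioConfig) -> DailySeries:
    """Draw one synthetic daily count series.

    x_t = round(max(0, mu_tau * (1 - depression) + trend * week
                       + amplitude * sin(2 pi t / 365) + eta_t)),
    with eta an AR(1) Gaussian noise.  Pure function of the config
    (including its seed).
    """
    rng = np.random.default_rng(config.seed)
    n = 7 * config.weeks
    depressed = {(w, d): f for w, d, f in config.holidays}
    eta = np.zeros(n)
    shocks = rng.normal(0.0, config.noise_sd, size=n)
    for t in range(n):
        eta[t] = config.ar_coefficient * (eta[t - 1] if t else 0.0) + shocks[t]
    values = np.empty(n)
    for t in range(n):
        week = t // 7 + 1
        tau = t % 7 + 1
        mu = config.weekday_profile[tau - 1]
        mu *= 1.0 - depressed.get((week, tau), 0.0)
        level = (
            mu
            + config.trend_per_week * week
            + config.annual_amplitude * np.sin(2 * np.pi * (t + 1) / 365.0)
            + eta[t]
        )
        values[t] = np.round(max(0.0, level))
    return DailySeries(DEFAULT_START, values, config.label)


def generate_ses_truth(
    weeks: int, tau_profile, alpha_true: float, noise_sd: float, seed: int
) -> WeekdayPanel:
    """Weekday panel whose sub-series follow the local-level process that a
    simple exponential smoother with constant ``alpha_true`` predicts
    optimally (an ARIMA(0,1,1) with theta = 1 - alpha).

    Ground truth for smoothing-constant recovery experiments; values are
    real, not rounded.
    """
    if not 0.0 < alpha_true < 1.0:
        raise ValueError(f"alpha_true must be in (0, 1), got {alpha_true}")
    profile = np.asarray(tau_profile, dtype=float)
    if profile.shape != (7,):
        raise ValueError("tau_profile needs exactly 7 values")
    rng = np.random.default_rng(seed)
    values = np.empty((weeks, 7))
    theta = 1.0 - alpha_true
    for j in range(7):
        eps = rng.normal(0.0, noise_sd, size=weeks + 1)
        x = np.empty(weeks)
        prev = profile[j]
        for i in range(weeks):
            x[i] = prev + eps[i + 1] - theta * eps[i]
            prev = x[i]
        values[:, j] = x
    return WeekdayPanel(DEFAULT_START, values, "ses-truth", 0)


# Published week-45 worked example: observed counts, the two arms'
# predictions and the combination weights, exactly as printed.
_WORKED_EXAMPLE = {
    "EOV": {
        "observed": (206.0, 193.0, 182.0, 171.0, 150.0, 86.0, 34.0),
        "arima": (194.40, 189.47, 194.27, 248.46, 197.90, 66.11, 41.00),
        "ses": (196.76, 195.68, 190.00, 256.56, 193.76, 76.33, 46.28),
        "l1": (0.53, 0.57, 0.58, 0.57, 0.46, 0.39, 0.46),
        "l2": (0.47, 0.43, 0.42, 0.43, 0.54, 0.61, 0.54),
    },
    "ROV": {
        "observed": (173.0, 178.0, 145.0, 161.0, 163.0, 18.0, 11.0),
        "arima": (197.32, 197.88, 160.23, 174.97, 121.83, 24.85, 18.03),
        "ses": (186.12, 196.28, 177.78, 185.36, 126.76, 27.32, 13.61),
        "l1": (0.52, 0.55, 0.51, 0.50, 0.48, 0.28, 0.36),
        "l2": (0.48, 0.45, 0.49, 0.50, 0.52, 0.72, 0.64),
    },
}


def worked_example_fixture() -> dict[str, dict[str, np.ndarray]]:
    """Week-45 observed values, arm predictions and weights for the EOV and
    ROV series (Monday..Sunday)."""
    return {
        series: {key: np.array(vals) for key, vals in rows.items()}
        for series, rows in _WORKED_EXAMPLE.items()
    }


def load_preset(name: str) -> ScenarioConfig:
    """Load a shipped scenario preset (``eov_like``, ``rov_like``,
    ``flat_control``)."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; available: {PRESETS}")
    text = (
        importlib.resources.files("ovforecast") / "presets" / f"{name}.yaml"
    ).read_text()
    raw = yaml.safe_load(text)
    raw["weekday_profile"] = tuple(raw["weekday_profile"])
    raw["holidays"] = tuple(tuple(h) for h in raw.get("holidays", []))
    return ScenarioConfig(**raw)
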