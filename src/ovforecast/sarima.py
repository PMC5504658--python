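"""Seasonal-ARIMA arm: lag-7 differencing, subset-lag ARMA estimation,
order selection, significance pruning, portmanteau diagnostics, forecasting.

The daily series is made stationary by seasonal differencing at the weekly
period (one application of ``1 - B^7`` by default), then a *subset* ARMA
model is fitted on the differenced scale:

    phi(B) w_t = Theta(B) eps_t,
    phi(B)   = 1 - sum_k phi_k B^k   over the AR lag set,
    Theta(B) = 1 - sum_k theta_k B^k over the MA lag set.

Estimation minimises the conditional sum of squares (presample errors set to
zero, conditioning on the first max-AR-lag observations) with a trust-region
least-squares optimiser started from the zero coefficient vector.  Candidate orders are
full contiguous-lag grids ranked by BIC; sparse lag sets then arise by
iteratively dropping coefficients whose |t| falls below a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal, stats

__all__ = [
    "DifferencingSpec",
    "SubsetArmaModel",
    "LjungBoxResult",
    "FitError",
    "difference",
    "invert_difference",
    "acf",
    "pacf",
    "fit_subset_arma",
    "select_orders_bic",
    "prune_insignificant",
    "ljung_box",
    "forecast",
]

_RSS_FLOOR = 1e-12


class FitError(RuntimeError):
    """Raised when the CSS optimiser fails to converge."""


@dataclass(frozen=True)
class DifferencingSpec:
    """Differencing applied before ARMA fitting: ``(1-B)^d`` then
    ``(1-B^D_lag)^D_order``.  Defaults model one weekly seasonal difference."""

    d: int = 0
    D_lag: int = 7
    D_order: int = 1

    def __post_init__(self) -> None:
        if self.d < 0 or self.D_order < 0 or self.D_lag < 1:
            raise ValueError(f"invalid differencing spec {self}")

    @property
    def offset(self) -> int:
        """Observations consumed by differencing."""
        return self.d + self.D_order * self.D_lag


def difference(series, spec: DifferencingSpec) -> np.ndarray:
    """Apply ``(1-B)^d`` then ``(1-B^s)^D`` to a sequence."""
    x = np.asarray(series, dtype=float)
    if len(x) <= spec.offset:
        raise ValueError(
            f"series of length {len(x)} too short for differencing offset {spec.offset}"
        )
    for _ in range(spec.d):
        x = np.diff(x)
    for _ in range(spec.D_order):
        x = x[spec.D_lag :] - x[: -spec.D_lag]
    return x


def invert_difference(diff_forecasts, history, spec: DifferencingSpec) -> np.ndarray:
    """Map forecasts on the differenced scale back to the original scale.

    ``history`` is the observed original-scale series the differencing was
    applied to; lagged values needed by the inversion come from it, and from
    previously inverted forecasts once the horizon exceeds the lag.
    """
    f = np.asarray(diff_forecasts, dtype=float)
    hist0 = np.asarray(history, dtype=float)
    if len(hist0) <= spec.offset:
        raise ValueError("history too short to invert differencing")
    # ladder of partially differenced histories, regular diffs first
    ladder = [hist0]
    for _ in range(spec.d):
        ladder.append(np.diff(ladder[-1]))
    for _ in range(spec.D_order):
        ladder.append(ladder[-1][spec.D_lag :] - ladder[-1][: -spec.D_lag])
    # undo seasonal differences, innermost last-applied first
    level = len(ladder) - 1
    for _ in range(spec.D_order):
        hist = ladder[level - 1]
        ext = list(hist)
        out = np.empty_like(f)
        for j in range(len(f)):
            out[j] = f[j] + ext[len(ext) - spec.D_lag]
            ext.append(out[j])
        f = out
        level -= 1
    # undo regular differences (cumulative sums from the last history value)
    for _ in range(spec.d):
        hist = ladder[level - 1]
        f = np.cumsum(f) + hist[-1]
        level -= 1
    return f


def acf(series, max_lag: int) -> np.ndarray:
    """Sample autocorrelations r_0..r_max_lag (r_0 = 1).

    r_k = sum_t (x_t - xbar)(x_{t+k} - xbar) / sum_t (x_t - xbar)^2.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if max_lag >= n:
        raise ValueError(f"max_lag {max_lag} must be < series length {n}")
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom == 0.0:
        raise ValueError("zero-variance series has undefined autocorrelation")
    r = np.empty(max_lag + 1)
    r[0] = 1.0
    for k in range(1, max_lag + 1):
        r[k] = float(xc[:-k] @ xc[k:]) / denom
    return r


def pacf(series, max_lag: int) -> np.ndarray:
    """Partial autocorrelations via the Durbin-Levinson recursion.

    Entry 0 is 1 by convention; entry k is phi_kk.
    """
    r = acf(series, max_lag)
    out = np.empty(max_lag + 1)
    out[0] = 1.0
    if max_lag == 0:
        return out
    phi_prev = np.array([r[1]])
    out[1] = r[1]
    for k in range(2, max_lag + 1):
        num = r[k] - phi_prev @ r[k - 1 : 0 : -1]
        den = 1.0 - phi_prev @ r[1:k]
        phi_kk = num / den
        phi = np.empty(k)
        phi[:-1] = phi_prev - phi_kk * phi_prev[::-1]
        phi[-1] = phi_kk
        out[k] = phi_kk
        phi_prev = phi
    return out


@dataclass
class LjungBoxResult:
    """Per-lag portmanteau test entries (lag, Q, df, p-value)."""

    entries: list[tuple[int, float, int, float]]

    def p_values(self) -> dict[int, float]:
        return {lag: p for lag, _, _, p in self.entries}

    def all_white(self, alpha: float = 0.05) -> bool:
        return all(p > alpha for p in self.p_values().values())


def ljung_box(residuals, lags, n_params: int = 0) -> LjungBoxResult:
    """Ljung-Box white-noise test at the given lags.

    Q(m) = n (n+2) sum_{k=1..m} r_k^2 / (n-k); the reference distribution is
    chi-square with df = m - n_params, floored at 1.
    """
    e = np.asarray(residuals, dtype=float)
    n = len(e)
    lag_list = sorted(int(m) for m in lags)
    if not lag_list or lag_list[0] < 1:
        raise ValueError("lags must be positive integers")
    if lag_list[-1] >= n:
        raise ValueError(f"lag {lag_list[-1]} >= series length {n}")
    r = acf(e, lag_list[-1])
    entries = []
    for m in lag_list:
        q = n * (n + 2) * float(np.sum(r[1 : m + 1] ** 2 / (n - np.arange(1, m + 1))))
        df = max(m - n_params, 1)
        p = float(stats.chi2.sf(q, df))
        entries.append((m, q, df, p))
    return LjungBoxResult(entries)


@dataclass
class SubsetArmaModel:
    """Subset-lag ARMA fit on a differenced series.

    ``ar_terms`` / ``ma_terms`` map lag -> coefficient under the sign
    convention phi(B) = 1 - sum phi_k B^k, Theta(B) = 1 - sum theta_k B^k.
    ``residuals_diff`` holds the conditional one-step errors eps_t aligned to
    the differenced series, with the warm-up prefix (first max-AR-lag
    entries) as NaN.  Because the differencing polynomial has unit leading
    coefficient, eps is also the one-step residual observed - fitted on the
    original scale.
    """

    ar_terms: dict[int, float]
    ma_terms: dict[int, float]
    noise_variance: float
    diff: DifferencingSpec
    residuals_diff: np.ndarray
    rss: float
    n_effective: int
    standard_errors: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def n_params(self) -> int:
        return len(self.ar_terms) + len(self.ma_terms)

    @property
    def warmup(self) -> int:
        return max(self.ar_terms, default=0)

    def fitted_original(self, original_series) -> np.ndarray:
        """One-step fitted values on the original scale, NaN over the warm-up
        prefix (differencing offset + max AR lag)."""
        x = np.asarray(original_series, dtype=float)
        off = self.diff.offset
        if len(x) != len(self.residuals_diff) + off:
            raise ValueError("original series does not match the fitted sample")
        fitted = np.full_like(x, np.nan)
        fitted[off:] = x[off:] - self.residuals_diff
        return fitted

    def residuals_original(self, original_series) -> np.ndarray:
        x = np.asarray(original_series, dtype=float)
        return x - self.fitted_original(x)

    def t_values(self) -> dict[str, float]:
        out = {}
        for name, coef in self._named_coefs():
            se = self.standard_errors.get(name, np.nan)
            out[name] = coef / se if se and np.isfinite(se) and se > 0 else np.inf
        return out

    def _named_coefs(self):
        for lag in sorted(self.ar_terms):
            yield f"ar{lag}", self.ar_terms[lag]
        for lag in sorted(self.ma_terms):
            yield f"ma{lag}", self.ma_terms[lag]

    def to_text(self) -> str:
        lines = [
            f"d = {self.diff.d}",
            f"D_lag = {self.diff.D_lag}",
            f"D_order = {self.diff.D_order}",
            f"sigma2 = {self.noise_variance!r}",
            f"n_effective = {self.n_effective}",
        ]
        for name, coef in self._named_coefs():
            lines.append(f"{name} = {coef!r}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "SubsetArmaModel":
        kv: dict[str, str] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            kv[key.strip()] = val.strip()
        diff = DifferencingSpec(
            d=int(kv.pop("d")), D_lag=int(kv.pop("D_lag")), D_order=int(kv.pop("D_order"))
        )
        sigma2 = float(kv.pop("sigma2"))
        n_eff = int(kv.pop("n_effective"))
        ar = {int(k[2:]): float(v) for k, v in kv.items() if k.startswith("ar")}
        ma = {int(k[2:]): float(v) for k, v in kv.items() if k.startswith("ma")}
        return cls(ar, ma, sigma2, diff, np.empty(0), sigma2 * n_eff, n_eff)


def _css_residuals(w: np.ndarray, ar_lags, ar_coefs, ma_lags, ma_coefs) -> np.ndarray:
    """Conditional one-step errors eps_t for t = max(ar_lags)..n-1.

    Conditions on the first max-AR-lag observations; presample eps are zero.
    """
    p = max(ar_lags, default=0)
    n = len(w)
    u = w[p:].copy()
    for lag, c in zip(ar_lags, ar_coefs):
        u -= c * w[p - lag : n - lag]
    if ma_lags:
        a = np.zeros(max(ma_lags) + 1)
        a[0] = 1.0
        for lag, c in zip(ma_lags, ma_coefs):
            a[lag] = -c
        # Theta(B) eps = u with zero initial conditions <=> eps_t = u_t + sum theta_k eps_{t-k}
        u = signal.lfilter([1.0], a, u)
    return u


def _unpack(beta: np.ndarray, ar_lags, ma_lags):
    k = len(ar_lags)
    return beta[:k], beta[k:]


def _css_rss(beta, w, ar_lags, ma_lags) -> float:
    # non-invertible MA regions make the error recursion explode; a large
    # finite penalty keeps the line search away without overflow noise
    ar_c, ma_c = _unpack(beta, ar_lags, ma_lags)
    with np.errstate(over="ignore", invalid="ignore"):
        eps = _css_residuals(w, ar_lags, ar_c, ma_lags, ma_c)
        rss = float(eps @ eps)
    return rss if np.isfinite(rss) else 1e300


def _numerical_hessian(fun, x0: np.ndarray, step: float = 1e-4) -> np.ndarray:
    k = len(x0)
    h = step * np.maximum(1.0, np.abs(x0))
    hess = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h[i]
            ej[j] = h[j]
            val = (
                fun(x0 + ei + ej)
                - fun(x0 + ei - ej)
                - fun(x0 - ei + ej)
                + fun(x0 - ei - ej)
            ) / (4 * h[i] * h[j])
            hess[i, j] = hess[j, i] = val
    return hess


def fit_subset_arma(
    diff_series,
    ar_lags,
    ma_lags,
    diff: DifferencingSpec | None = None,
) -> SubsetArmaModel:
    """Fit a subset-lag ARMA model to a (differenced) series by conditional
    least squares.

    Coefficients start at zero and are optimised by trust-region least
    squares on the vector of conditional errors.  Standard errors come from the numerical
    Hessian of the objective (cov = 2 sigma^2 H^-1).  A non-stationary AR
    root records a warning on the model rather than failing.
    """
    w = np.asarray(diff_series, dtype=float)
    ar_lags = sorted(int(l) for l in ar_lags)
    ma_lags = sorted(int(l) for l in ma_lags)
    if any(l < 1 for l in ar_lags + ma_lags):
        raise ValueError("lags must be positive")
    p = max(ar_lags, default=0)
    if len(w) <= p + max(ma_lags, default=0) + 1:
        raise ValueError("series too short for the requested lag sets")
    if diff is None:
        diff = DifferencingSpec(d=0, D_lag=7, D_order=0)
    k = len(ar_lags) + len(ma_lags)
    warnings: list[str] = []

    if k == 0:
        eps = w[p:].copy()
        beta = np.empty(0)
    else:

        def resid_vec(beta):
            ar_c, ma_c = _unpack(beta, ar_lags, ma_lags)
            with np.errstate(over="ignore", invalid="ignore"):
                eps = _css_residuals(w, ar_lags, ar_c, ma_lags, ma_c)
            return np.nan_to_num(eps, nan=1e100, posinf=1e100, neginf=-1e100)

        res = optimize.least_squares(
            resid_vec, np.zeros(k), method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-10
        )
        if res.status <= 0:
            raise FitError(f"CSS optimisation did not converge: {res.message}")
        beta = res.x
        ar_c, ma_c = _unpack(beta, ar_lags, ma_lags)
        eps = _css_residuals(w, ar_lags, ar_c, ma_lags, ma_c)

    rss = float(eps @ eps)
    n_eff = len(eps)
    sigma2 = rss / n_eff
    ar_terms = {l: float(c) for l, c in zip(ar_lags, beta[: len(ar_lags)])}
    ma_terms = {l: float(c) for l, c in zip(ma_lags, beta[len(ar_lags) :])}

    ses: dict[str, float] = {}
    if k > 0 and rss > _RSS_FLOOR:
        hess = _numerical_hessian(lambda b: _css_rss(b, w, ar_lags, ma_lags), beta)
        try:
            cov = 2.0 * sigma2 * np.linalg.inv(hess)
            variances = np.diag(cov)
        except np.linalg.LinAlgError:
            variances = np.full(k, np.nan)
            warnings.append("singular Hessian; standard errors unavailable")
        names = [f"ar{l}" for l in ar_lags] + [f"ma{l}" for l in ma_lags]
        for name, v in zip(names, variances):
            ses[name] = float(np.sqrt(v)) if v > 0 else np.nan

    if ar_terms:
        poly = np.zeros(max(ar_lags) + 1)
        poly[0] = 1.0
        for lag, c in ar_terms.items():
            poly[lag] = -c
        roots = np.roots(poly[::-1])
        if np.any(np.abs(roots) <= 1.0 + 1e-10):
            warnings.append("non-stationary AR polynomial (root on/inside unit circle)")

    residuals_aligned = np.concatenate([np.full(p, np.nan), eps])
    return SubsetArmaModel(
        ar_terms=ar_terms,
        ma_terms=ma_terms,
        noise_variance=sigma2,
        diff=diff,
        residuals_diff=residuals_aligned,
        rss=rss,
        n_effective=n_eff,
        standard_errors=ses,
        warnings=warnings,
    )


def select_orders_bic(
    diff_series, p_max: int = 7, q_max: int = 7
) -> tuple[set[int], set[int]]:
    """Pick contiguous ARMA(p, q) lag sets by minimum BIC.

    BIC = n ln(RSS/n) + k ln(n) with k = p + q + 1 (the innovation variance
    counts as a parameter).  Ties break toward smaller p + q, then smaller p.
    """
    w = np.asarray(diff_series, dtype=float)
    n = len(w)
    best = None
    failures = []
    for p in range(p_max + 1):
        for q in range(q_max + 1):
            try:
                model = fit_subset_arma(w, range(1, p + 1), range(1, q + 1))
            except (FitError, ValueError) as exc:
                failures.append((p, q, str(exc)))
                continue
            rss = max(model.rss, _RSS_FLOOR)
            bic = n * np.log(rss / n) + (p + q + 1) * np.log(n)
            key = (bic, p + q, p)
            if best is None or key < best[0]:
                best = (key, p, q)
    if best is None:
        raise FitError(f"all candidate fits failed: {failures}")
    _, p, q = best
    return set(range(1, p + 1)), set(range(1, q + 1))


def prune_insignificant(
    model: SubsetArmaModel, diff_series, t_threshold: float = 1.96
) -> SubsetArmaModel:
    """Iteratively drop the least significant coefficient and refit.

    At each step the term with the smallest |t| below the threshold is
    removed; stops when every remaining |t| meets the threshold or no terms
    remain.
    """
    w = np.asarray(diff_series, dtype=float)
    current = model
    while current.n_params > 0:
        tvals = current.t_values()
        name, tmin = min(tvals.items(), key=lambda kv: abs(kv[1]))
        if abs(tmin) >= t_threshold:
            break
        lag = int(name[2:])
        ar = sorted(current.ar_terms)
        ma = sorted(current.ma_terms)
        if name.startswith("ar"):
            ar.remove(lag)
        else:
            ma.remove(lag)
        current = fit_subset_arma(w, ar, ma, diff=current.diff)
    return current


def forecast(model: SubsetArmaModel, history, horizon: int = 7) -> np.ndarray:
    """Multi-step forecast on the original scale.

    ARMA recursion on the differenced scale with future errors set to zero
    and in-sample conditional residuals for past errors, then differencing is
    inverted against the observed history.  Values are not clipped.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    x = np.asarray(history, dtype=float)
    w = difference(x, model.diff)
    p = max(model.ar_terms, default=0)
    ar_c = [model.ar_terms[l] for l in sorted(model.ar_terms)]
    eps = _css_residuals(
        w,
        sorted(model.ar_terms),
        ar_c,
        sorted(model.ma_terms),
        [model.ma_terms[l] for l in sorted(model.ma_terms)],
    )
    w_ext = list(w)
    eps_ext = [0.0] * p + list(eps)
    w_fore = []
    n = len(w)
    for h in range(horizon):
        t = n + h
        val = 0.0
        for lag, c in model.ar_terms.items():
            val += c * w_ext[t - lag]
        for lag, c in model.ma_terms.items():
            val -= c * eps_ext[t - lag]
        w_ext.append(val)
        eps_ext.append(0.0)
        w_fore.append(val)
    return invert_difference(np.array(w_fore), x, model.diff)
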