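"""Exponential-decay models of windowed HRV and their comparison.

Three two-parameter models describe how SDRR falls during a graded exercise
test, differing only in the predictor x_j:

    SDRR_j = b * 2^(-x_j / tau)        x_j = mean HR (model 1, beats/min)
                                       x_j = mean power (model 2, W)
                                       x_j = mean work intensity (model 3, %VO2max)

``tau`` is the HRV decay constant — the predictor increase that halves
SDRR — and ``b`` the HRV intercept, the SDRR extrapolated to predictor
zero. Fits are unweighted nonlinear least squares on the untransformed
SDRR, seeded by an ordinary least-squares line on log SDRR; models are
compared by AIC/BIC under a Gaussian likelihood with the error variance
counted as a parameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

MODEL_PREDICTOR = {1: "hr_bpm", 2: "p_w", 3: "i_pct"}
EFFORT_RANGES = ("full", "effort")


class FitError(RuntimeError):
    pass


@dataclass
class DecayFit:
    """One fitted exponential decay of windowed SDRR."""

    model: int  # 1: HR, 2: power, 3: work intensity
    effort_range: str  # "full" (pre + effort + recovery) or "effort"
    b: float  # ms
    tau: float  # predictor units
    se_b: float
    se_tau: float
    p_b: float
    p_tau: float
    rss: float  # ms^2
    n: int  # windows used
    k_params: int = 2

    def predict(self, x):
        return self.b * 2.0 ** (-np.asarray(x, dtype=float) / self.tau)

    @property
    def loglik(self) -> float:
        """Gaussian log-likelihood at the optimum, sigma^2 = RSS/n."""
        if self.rss <= 0:
            return np.inf
        return -0.5 * self.n * (np.log(2 * np.pi) + np.log(self.rss / self.n) + 1.0)

    @property
    def aic(self) -> float:
        k = self.k_params + 1  # error variance counted as a parameter
        return 2 * k - 2 * self.loglik

    @property
    def bic(self) -> float:
        k = self.k_params + 1
        return k * np.log(self.n) - 2 * self.loglik

    def to_dict(self) -> dict:
        return {
            "model": self.model, "effort_range": self.effort_range,
            "b": self.b, "tau": self.tau, "se_b": self.se_b, "se_tau": self.se_tau,
            "p_b": self.p_b, "p_tau": self.p_tau, "rss": self.rss, "n": self.n,
            "aic": self.aic, "bic": self.bic,
        }


def information_criteria(fit: DecayFit) -> tuple[float, float]:
    """(AIC, BIC) of a converged fit; -inf sentinels when RSS is zero."""
    if fit.rss <= 0:
        return -np.inf, -np.inf
    return fit.aic, fit.bic


def _decay(x, b, tau):
    return b * 2.0 ** (-x / tau)


def fit_decay(
    windows: pd.DataFrame,
    model: int = 1,
    effort_range: str = "full",
) -> DecayFit:
    """Nonlinear least-squares fit of one decay model to a window table.

    ``windows`` is the table from :func:`hrvdecay.windows.windowed_hrv` (or a
    concatenation over subjects). Windows with non-positive or missing SDRR
    or predictor are excluded. Initial values come from the OLS line of
    ln(SDRR) on the predictor; if that seed fails to converge, a grid of
    starting decay constants spanning the predictor range is tried.
    """
    if model not in MODEL_PREDICTOR:
        raise ValueError(f"model must be 1, 2 or 3, got {model}")
    if effort_range not in EFFORT_RANGES:
        raise ValueError(f"effort_range must be one of {EFFORT_RANGES}")
    df = windows
    if effort_range == "effort":
        df = df[df["phase"] == "effort"]
    x = df[MODEL_PREDICTOR[model]].to_numpy(dtype=float)
    y = df["sdrr_ms"].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y) & (y > 0)
    x, y = x[ok], y[ok]
    if x.size < 4:
        raise FitError(f"need >= 4 usable windows, got {x.size}")

    # log-linear seed
    slope, intercept = np.polyfit(x, np.log(y), 1)
    seeds = []
    if slope < 0:
        seeds.append((np.exp(intercept), -np.log(2) / slope))
    span = max(x.max() - x.min(), 1.0)
    for frac in (0.5, 0.25, 1.0, 0.1, 2.0):
        seeds.append((y.max() * 2.0 ** (x.min() / (span * frac)), span * frac))

    last_err: Exception | None = None
    for b0, tau0 in seeds:
        try:
            popt, pcov = optimize.curve_fit(
                _decay, x, y, p0=[b0, tau0], bounds=([0, 0], [np.inf, np.inf]),
                maxfev=20000,
            )
            if not np.all(np.isfinite(popt)):
                raise RuntimeError("non-finite optimum")
            break
        except Exception as err:  # noqa: BLE001 - scipy raises bare RuntimeError
            last_err = err
    else:
        raise FitError(f"decay fit did not converge over seed grid {seeds}") from last_err

    b, tau = (float(v) for v in popt)
    resid = y - _decay(x, b, tau)
    rss = float(resid @ resid)
    se = np.sqrt(np.maximum(np.diag(pcov), 0.0))
    dof = max(x.size - 2, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_b = b / se[0] if se[0] > 0 else np.inf
        t_tau = tau / se[1] if se[1] > 0 else np.inf
    p_b = float(2 * stats.t.sf(abs(t_b), dof))
    p_tau = float(2 * stats.t.sf(abs(t_tau), dof))
    return DecayFit(model, effort_range, b, tau, float(se[0]), float(se[1]),
                    p_b, p_tau, rss, int(x.size))


def compare_models(
    windows: pd.DataFrame,
    models=(1, 2, 3),
    effort_ranges=EFFORT_RANGES,
) -> pd.DataFrame:
    """Fit every (model, range) combination and tabulate AIC/BIC ranking.

    Returns a table with one row per fit, sorted within each range by AIC,
    with a ``rank`` column (1 = lowest AIC).
    """
    rows = []
    for rng_ in effort_ranges:
        fits = [fit_decay(windows, m, rng_) for m in models]
        order = np.argsort([f.aic for f in fits])
        for rank, k in enumerate(order, start=1):
            d = fits[k].to_dict()
            d["rank"] = rank
            rows.append(d)
    return pd.DataFrame(rows)
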