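"""Detrending of RR series during graded exercise.

Two detrenders are provided:

* an ODE detrender: the slow, workload-driven RR trend is modelled by the
  first-order linear differential equation

      rr'(t) = c0 + c1 * rr(t) + c2 * P(t)

  driven by the instantaneous power P(t). The coefficients are estimated in
  two steps — a generalized-cross-validated smoothing spline gives the time
  derivative of RR, then an ordinary least-squares regression of that
  derivative on (1, rr_smooth, P) gives (c0, c1, c2) — and the trend is
  produced by numerically integrating the equation with the estimated
  coefficients. For a stable fit c1 < 0, and the physical parameters are
  time_constant = -1/c1 (s), gain = -c2/c1 (ms per W of steady-state RR
  drop) and baseline = -c0/c1 (ms, resting equilibrium RR).

* a local polynomial detrender: at each beat i an order-p polynomial is fit
  by least squares in a centered window of omega beats and its prediction at
  i is subtracted. This is the classical moving-polynomial detrend used in
  the sensitivity analysis; windows are clipped at the series boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import make_smoothing_spline
from scipy.signal import savgol_filter

from .preprocess import RRSeries


class DetrendError(ValueError):
    pass


@dataclass
class TrendFit:
    """Fitted first-order ODE trend of an RR series."""

    c0: float  # ms/s
    c1: float  # 1/s
    c2: float  # ms/(W s)
    trend_ms: np.ndarray  # trend at beat times
    x_det_ms: np.ndarray  # detrended residuals, x - trend
    r2: float  # squared Pearson correlation of trend vs measured RR
    unstable: bool = False  # c1 >= 0: no relaxing equilibrium

    @property
    def time_constant_s(self) -> float:
        return -1.0 / self.c1

    @property
    def gain_ms_per_w(self) -> float:
        # steady-state RR drop per watt: rr_eq(P) = -(c0 + c2 P)/c1
        return self.c2 / self.c1

    @property
    def baseline_ms(self) -> float:
        return -self.c0 / self.c1

    def to_dict(self) -> dict:
        return {
            "c0": self.c0, "c1": self.c1, "c2": self.c2,
            "time_constant_s": self.time_constant_s,
            "gain_ms_per_w": self.gain_ms_per_w,
            "baseline_ms": self.baseline_ms,
            "r2": self.r2, "unstable": self.unstable,
        }


@dataclass(frozen=True)
class PolyDetrendConfig:
    """Order and window of the local polynomial detrender."""

    p: int
    omega: int

    def __post_init__(self) -> None:
        if self.p not in (0, 1, 2):
            raise DetrendError(f"polynomial order must be 0, 1 or 2, got {self.p}")
        if self.omega % 2 == 0:
            raise DetrendError("omega must be odd")
        if self.omega < self.p + 2:
            raise DetrendError("omega must be at least p + 2")


def _local_noise_scale(y: np.ndarray, window: int = 201) -> np.ndarray:
    """Rolling robust estimate of the beat-to-beat noise SD.

    Uses the centered rolling median of |successive differences|; for iid
    Gaussian noise of SD sigma the median absolute difference is
    sqrt(2) * 0.6745 * sigma.
    """
    import pandas as pd

    d = np.abs(np.diff(y, prepend=y[0] if y.size else 0.0))
    med = pd.Series(d).rolling(window, center=True, min_periods=1).median().to_numpy()
    return np.maximum(med / (np.sqrt(2.0) * 0.6745), 1e-6)


def estimate_derivative(t, y, smoothing: float | None = None, weighted: bool = True):
    """Smoothing-spline estimate of dy/dt at the sample times.

    Fits a cubic smoothing spline of y(t) — the penalty is chosen by
    generalized cross-validation unless ``smoothing`` (the penalty lambda)
    is given — and returns ``(dy_dt, y_smooth)`` evaluated at ``t``.

    HRV noise is strongly heteroscedastic (two orders of magnitude larger
    at rest than at peak heart rate), so by default observations are
    weighted by the inverse variance of a rolling robust noise estimate;
    without weights a single GCV penalty oversmooths the low-noise,
    high-curvature segments and attenuates the derivative.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size < 10:
        raise DetrendError("need at least 10 points for derivative estimation")
    if np.any(np.diff(t) <= 0):
        raise DetrendError("t must be strictly increasing")
    w = None
    if weighted:
        w = 1.0 / _local_noise_scale(y) ** 2
        w = w * (t.size / w.sum())
    spl = make_smoothing_spline(t, y, w=w, lam=smoothing)
    return spl.derivative()(t), spl(t)


def _rk4_affine(c1: float, u_nodes: np.ndarray, u_mids: np.ndarray,
                h: np.ndarray, y0: float) -> np.ndarray:
    """Fixed-step RK4 for the affine ODE y' = c1*y + u(t).

    ``u_nodes[i]`` is the forcing at grid node i, ``u_mids[i]`` at the
    midpoint of interval i, ``h[i]`` the interval length.
    """
    n = h.size
    if n and np.ptp(h) < 1e-12 * h[0]:
        # uniform step: the RK4 update y_{i+1} = G*y_i + d_i is a linear
        # recurrence, evaluated in C via an IIR filter
        from scipy.signal import lfilter

        a = h[0] * c1
        G = 1.0 + a + a**2 / 2.0 + a**3 / 6.0 + a**4 / 24.0
        d = (h[0] / 6.0) * ((1.0 + a + a**2 / 2.0 + a**3 / 4.0) * u_nodes[:-1]
                            + (4.0 + 2.0 * a + a**2 / 2.0) * u_mids
                            + u_nodes[1:])
        x = np.concatenate(([y0], d))
        return lfilter([1.0], [1.0, -G], x)
    out = np.empty(n + 1)
    out[0] = y = y0
    for i in range(n):
        hi = h[i]
        un, um, un1 = u_nodes[i], u_mids[i], u_nodes[i + 1]
        k1 = c1 * y + un
        k2 = c1 * (y + hi / 2 * k1) + um
        k3 = c1 * (y + hi / 2 * k2) + um
        k4 = c1 * (y + hi * k3) + un1
        y = y + hi / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        out[i + 1] = y
    return out


def integrate_ode(c0: float, c1: float, c2: float, power, rr0: float, t_grid) -> np.ndarray:
    """Integrate rr' = c0 + c1*rr + c2*P(t) on ``t_grid`` from rr(t_grid[0]) = rr0.

    Classical fixed-step fourth-order Runge-Kutta, one step per grid
    interval. ``power`` is a callable P(t) in watts.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    h = np.diff(t_grid)
    u_nodes = c0 + c2 * np.asarray(power(t_grid), dtype=float)
    u_mids = c0 + c2 * np.asarray(power(t_grid[:-1] + h / 2), dtype=float)
    out = _rk4_affine(c1, u_nodes, u_mids, h, rr0)
    if not np.all(np.isfinite(out)):
        raise DetrendError("ODE integration produced non-finite trend")
    return out


def trend_at_beats(c0, c1, c2, power, rr0, t_beats, grid_step_s: float = 1.0) -> np.ndarray:
    """ODE trend evaluated at beat times via a fixed 1 Hz integration grid."""
    t_beats = np.asarray(t_beats, dtype=float)
    t0, t1 = float(t_beats[0]), float(t_beats[-1])
    n = int(np.ceil((t1 - t0) / grid_step_s)) + 1
    grid = t0 + grid_step_s * np.arange(n + 1)
    trend_grid = integrate_ode(c0, c1, c2, power, rr0, grid)
    return np.interp(t_beats, grid, trend_grid)


def _two_step_coefficients(rr: RRSeries, power, smoothing, stride: int = 1):
    """Spline-derivative + OLS estimate of (c0, c1, c2) and smoothed rr0."""
    t, y = rr.t_s[::stride], rr.rr_ms[::stride]
    dy, y_s = estimate_derivative(t, y, smoothing)
    p = np.asarray(power(t), dtype=float)
    y_const = np.ptp(y_s) <= 1e-9 * max(1.0, float(np.abs(y_s).max()))
    p_const = np.ptp(p) <= 1e-9 * max(1.0, float(np.abs(p).max()))
    if y_const and p_const:
        raise DetrendError("singular trend regression: constant RR and constant power")
    # near-collinear regressors (e.g. oversmoothed rr tracking the power ramp)
    # still give a usable minimum-norm seed for the refinement stage
    X = np.column_stack([np.ones_like(y_s), y_s, p])
    coef, *_ = np.linalg.lstsq(X, dy, rcond=None)
    return tuple(float(c) for c in coef), float(y_s[0])


def _profile_refine(rr: RRSeries, power, c1_seed: float,
                    grid_step_s: float = 1.0) -> tuple[float, float, float, float]:
    """Weighted least-squares refinement of the integrated trend.

    For fixed c1 the RK4 solution is linear in (rr0, c0, c2) by
    superposition, so the profile objective is a scalar function of c1:
    the inner problem is a weighted linear least squares onto the basis
    {e^{c1 t}, step response, power response}. Weights are the inverse
    variance of the local beat-to-beat noise, so the low-noise high-HR
    segment constrains the trend as strongly as the noisy rest segment.
    Returns (c0, c1, c2, rr0).
    """
    from scipy.optimize import minimize_scalar

    t, y = rr.t_s, rr.rr_ms
    t0, t1 = float(t[0]), float(t[-1])
    n = int(np.ceil((t1 - t0) / grid_step_s))
    grid = t0 + grid_step_s * np.arange(n + 1)
    h = np.diff(grid)
    p_nodes = np.asarray(power(grid), dtype=float)
    p_mids = np.asarray(power(grid[:-1] + h / 2), dtype=float)
    ones_n, ones_m = np.ones_like(p_nodes), np.ones_like(p_mids)
    zeros_n, zeros_m = np.zeros_like(p_nodes), np.zeros_like(p_mids)

    w = 1.0 / _local_noise_scale(y) ** 2
    w = w * (t.size / w.sum())
    sw = np.sqrt(w)

    def design(c1: float) -> np.ndarray:
        cols = []
        for u_n, u_m, y0 in ((zeros_n, zeros_m, 1.0),  # homogeneous
                             (ones_n, ones_m, 0.0),    # response to c0
                             (p_nodes, p_mids, 0.0)):  # response to c2*P
            sol = _rk4_affine(c1, u_n, u_m, h, y0)
            cols.append(np.interp(t, grid, sol))
        return np.column_stack(cols)

    def objective(c1: float) -> float:
        M = design(c1)
        coef, *_ = np.linalg.lstsq(sw[:, None] * M, sw * y, rcond=None)
        resid = y - M @ coef
        return float(w @ resid**2)

    # generous bounds around the two-step seed (time constants 2 s - 30 min)
    lo, hi = -0.5, -5e-4
    if np.isfinite(c1_seed) and c1_seed < 0:
        lo = max(lo, 8.0 * c1_seed)
    res = minimize_scalar(objective, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-6})
    c1 = float(res.x)
    M = design(c1)
    coef, *_ = np.linalg.lstsq(sw[:, None] * M, sw * y, rcond=None)
    rr0, a0, a2 = (float(c) for c in coef)
    return a0, c1, a2, rr0


def fit_ode(rr: RRSeries, power, smoothing: float | None = None,
            refine: bool = True) -> TrendFit:
    """Estimate the first-order RR trend and detrended residuals.

    Two-step estimation first: rr'(t) from a GCV smoothing spline, then
    OLS of the derivative on (1, rr_smooth, P(t)). With stepwise power the
    spline smears the derivative discontinuities at the load steps, which
    attenuates the coefficients, so by default the two-step estimate only
    seeds a profile least-squares refinement of the integrated equation
    (``refine=False`` gives the raw two-step fit). The trend is the
    numerically integrated equation from the fitted initial RR.
    """
    t, y = rr.t_s, rr.rr_ms
    stride = 3 if (refine and t.size > 1200) else 1
    (c0, c1, c2), rr0 = _two_step_coefficients(rr, power, smoothing, stride=stride)
    if refine:
        c0, c1, c2, rr0 = _profile_refine(rr, power, c1)

    unstable = c1 >= 0
    if unstable:
        warnings.warn("fitted c1 >= 0: trend has no stable equilibrium", stacklevel=2)

    trend = trend_at_beats(c0, c1, c2, power, rr0, t)
    x_det = y - trend
    r = np.corrcoef(trend, y)[0, 1]
    return TrendFit(c0, c1, c2, trend, x_det, float(r**2), unstable)


def detrend_ode(rr: RRSeries, power, smoothing: float | None = None):
    """Fit the ODE trend and subtract it; returns (x_det, TrendFit)."""
    fit = fit_ode(rr, power, smoothing)
    return fit.x_det_ms, fit


def detrend_poly(x, cfg: PolyDetrendConfig) -> np.ndarray:
    """Local polynomial detrend: subtract the centered-window LSQ prediction.

    Interior points use the Savitzky-Golay smoother (identical to evaluating
    the windowed least-squares polynomial at the window center); the first
    and last (omega-1)/2 points refit on the window truncated to available
    data, so a global degree-<=p trend is annihilated everywhere.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < cfg.omega:
        raise DetrendError(f"series length {n} shorter than omega {cfg.omega}")
    fitted = savgol_filter(x, window_length=cfg.omega, polyorder=cfg.p)
    half = (cfg.omega - 1) // 2
    for i in range(half):
        for j in (i, n - 1 - i):
            lo, hi = max(0, j - half), min(n, j + half + 1)
            u = np.arange(lo, hi) - j
            coeffs = np.polynomial.polynomial.polyfit(u, x[lo:hi], cfg.p)
            fitted[j] = coeffs[0]
    return x - fitted
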