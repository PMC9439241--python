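"""Synthetic graded-exercise-test generator.

Emulates the statistical structure of beat-to-beat RR recordings during an
incremental cycling test so that every downstream stage (cleaning,
detrending, windowed SDRR, decay fitting, cohort correlation) is testable
without external data.

Generative model per subject
----------------------------
* RR trend: first-order relaxation driven by the protocol power,
  rr'(t) = (rr_rest - gain * P(t) - rr(t)) / tau_hr, integrated by
  fixed-step RK4 at 1 Hz from rr(0) = rr_rest.
* Beats: emitted sequentially, t_{i+1} = t_i + rr_i / 1000, with
  rr_i = trend(t_i) + eps_i. The residual eps_i is Gaussian with standard
  deviation b_true * 2^(-HR_trend / tau_true) where HR_trend = 60000/trend:
  heart-rate variability shrinks exponentially as heart rate climbs,
  halving every ``tau_true`` beats/min. An optional AR(1) coefficient adds
  serial correlation to the residuals (default 0, independent beats).
* VO2: the same first-order form with a shorter time constant (oxygen
  uptake kinetics are faster than heart-rate kinetics), scaled so its
  maximum equals the subject's VO2max; sampled at 1 Hz.
* Cohort: per-subject decay constants tau_true are drawn with a chosen
  correlation (``coupling``) to VO2max through a Gaussian copula, and the
  intercept b_true loads positively on fitness, so fitter subjects have
  higher low-HR variability and faster decay when coupling < 0.

Defaults put the cohort at the scale of a regional-level adolescent-athlete
study: 18 subjects, ~2400-3500 beats per test, peak heart rate near
187 beats/min, ensemble decay parameters b = 1325 ms and
tau = 19.6 beats/min.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .preprocess import RRSeries
from .protocol import GETProtocol, make_protocol


class GenerationError(ValueError):
    pass


@dataclass(frozen=True)
class CRFIndices:
    """Cardiorespiratory fitness indices of one subject."""

    vo2max: float  # mL/kg/min
    map_w: float  # maximal aerobic power, W (last completed step)
    pvt1_w: float  # power at first ventilatory threshold, W
    pvt2_w: float  # power at second ventilatory threshold, W
    peak_hr: float | None = None  # beats/min, filled from the trajectory
    hrr: float | None = None  # 60 s heart-rate recovery, beats/min

    def __post_init__(self) -> None:
        for name in ("vo2max", "map_w", "pvt1_w", "pvt2_w"):
            if getattr(self, name) <= 0:
                raise GenerationError(f"{name} must be positive")
        if not (self.pvt1_w < self.pvt2_w < self.map_w):
            raise GenerationError("need pvt1 < pvt2 < map")


@dataclass(frozen=True)
class SubjectTruth:
    """Generative ground truth for one subject."""

    rr_rest: float  # ms, resting equilibrium RR
    ode_gain: float  # ms/W, steady-state RR drop per watt
    ode_tau: float  # s, RR kinetics time constant
    vo2_tau: float  # s, VO2 kinetics time constant (< ode_tau)
    b_true: float  # ms, HRV intercept of the decay law
    tau_true: float  # beats/min, HRV halving constant
    crf: CRFIndices
    exhaustion_power: float  # W, last completed step (= crf.map_w)
    ar1: float = 0.0  # residual AR(1) coefficient

    def __post_init__(self) -> None:
        for name in ("rr_rest", "ode_gain", "ode_tau", "vo2_tau", "b_true", "tau_true"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) < 0:
                raise GenerationError(f"{name} must be finite and non-negative")
        if self.vo2_tau >= self.ode_tau:
            raise GenerationError("vo2_tau must be smaller than ode_tau")
        if not -1 < self.ar1 < 1:
            raise GenerationError("ar1 must be in (-1, 1)")


@dataclass(frozen=True)
class ArtifactSpec:
    """Rates of the three injected artifact families (fractions of beats)."""

    spike_rate: float = 0.0002  # effort-phase spikes > 1000 ms
    ratio_outlier_rate: float = 0.0002  # >=2.5x or <=0.4x the local median
    jump_rate: float = 0.005  # increments > 10x the local median increment
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("spike_rate", "ratio_outlier_rate", "jump_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise GenerationError(f"{name} must be in [0, 1]")


@dataclass
class SubjectData:
    """One simulated test: RR series, VO2 series, fitness indices, truth."""

    rr: RRSeries
    vo2_t_s: np.ndarray
    vo2: np.ndarray  # mL/kg/min at vo2_t_s
    crf: CRFIndices
    truth: SubjectTruth
    protocol: GETProtocol
    trend_ms: np.ndarray  # noiseless RR trend at beat times (ground truth)
    artifact_idx: dict[str, np.ndarray] = field(default_factory=dict)


def _ode_coefficients(truth: SubjectTruth) -> tuple[float, float, float]:
    """(c0, c1, c2) of rr' = c0 + c1*rr + c2*P for the generative relaxation."""
    return truth.rr_rest / truth.ode_tau, -1.0 / truth.ode_tau, -truth.ode_gain / truth.ode_tau


def simulate_subject(protocol: GETProtocol, truth: SubjectTruth, seed) -> SubjectData:
    """Simulate one graded exercise test for one subject.

    Returns beats with exact time bookkeeping (t_{i+1} - t_i = rr_i/1000), a
    1 Hz VO2 series scaled to the subject's VO2max, and fitness indices made
    consistent with the trajectory: peak HR from the trend's minimum RR and
    HRR from the trend HR drop over the first 60 s of recovery.
    """
    rng = np.random.default_rng(seed)
    c0, c1, c2 = _ode_coefficients(truth)
    T = protocol.duration_s
    grid = np.arange(0.0, T + 1.0, 1.0)

    from .detrend import integrate_ode

    trend_grid = integrate_ode(c0, c1, c2, protocol.power_at, truth.rr_rest, grid)
    if np.any(trend_grid <= 0):
        raise GenerationError(
            f"RR trend became non-positive (rr_rest={truth.rr_rest}, "
            f"gain={truth.ode_gain}, map={truth.exhaustion_power}): gain too large"
        )

    # sequential beat emission along the trend
    t_list: list[float] = []
    rr_list: list[float] = []
    trend_list: list[float] = []
    t = 0.0
    prev_eps = 0.0
    prev_sigma = None
    phi = truth.ar1
    while t < T:
        trend_t = float(np.interp(t, grid, trend_grid))
        hr_trend = 60000.0 / trend_t
        sigma = truth.b_true * 2.0 ** (-hr_trend / truth.tau_true) if truth.b_true > 0 else 0.0
        z = rng.standard_normal()
        if phi != 0.0 and prev_sigma is not None and sigma > 0:
            eps = phi * prev_eps * (sigma / prev_sigma) + np.sqrt(1 - phi**2) * sigma * z
        else:
            eps = sigma * z
        rr_i = max(trend_t + eps, 1.0)
        t_list.append(t)
        rr_list.append(rr_i)
        trend_list.append(trend_t)
        prev_eps, prev_sigma = eps, sigma if sigma > 0 else None
        t += rr_i / 1000.0

    t_beats = np.array(t_list)
    rr_ms = np.array(rr_list)
    phases = np.asarray(protocol.phase_at(t_beats))
    rr_series = RRSeries(t_beats, rr_ms, phases)

    # VO2: first-order kinetics, faster than HR, rescaled to VO2max
    vo2_rest = 5.0  # mL/kg/min, seated rest
    k = (truth.crf.vo2max - vo2_rest) / truth.exhaustion_power
    a0, a1, a2 = vo2_rest / truth.vo2_tau, -1.0 / truth.vo2_tau, k / truth.vo2_tau
    vo2_raw = integrate_ode(a0, a1, a2, protocol.power_at, vo2_rest, grid)
    vo2 = vo2_raw * (truth.crf.vo2max / vo2_raw.max())

    # trajectory-consistent fitness indices
    peak_hr = 60000.0 / float(trend_grid.min())
    t_end_effort = next(e for ph, s, e in protocol.phase_spans() if ph == "effort")
    hr_cess = 60000.0 / float(np.interp(t_end_effort, grid, trend_grid))
    hr_60 = 60000.0 / float(np.interp(t_end_effort + 60.0, grid, trend_grid))
    crf = replace(truth.crf, peak_hr=peak_hr, hrr=hr_cess - hr_60)

    trend_beats = np.array(trend_list)
    return SubjectData(rr_series, grid, vo2, crf, replace(truth, crf=crf),
                       protocol, trend_beats)


def inject_artifacts(data: SubjectData, spec: ArtifactSpec) -> SubjectData:
    """Return a copy of ``data`` with electrode-style artifacts injected.

    Three families mimic connection errors: spikes above 1000 ms during
    effort, multiplicative outliers beyond [0.4, 2.5] times the local median
    RR, and jumps larger than 10 times the local median absolute increment.
    Injected beat indices are recorded per family in ``artifact_idx``.
    """
    rng = np.random.default_rng(spec.seed)
    rr = data.rr.rr_ms.copy()
    n = rr.size
    import pandas as pd

    local_med = pd.Series(rr).rolling(201, center=True, min_periods=1).median().to_numpy()
    inc_med = (
        pd.Series(np.abs(np.diff(rr, prepend=rr[0])))
        .rolling(201, center=True, min_periods=1)
        .median()
        .to_numpy()
    )

    effort_idx = np.flatnonzero(data.rr.phase == "effort")
    taken: set[int] = set()

    def pick(candidates: np.ndarray, count: int) -> np.ndarray:
        pool = np.array([i for i in candidates if i not in taken])
        count = min(count, pool.size)
        chosen = rng.choice(pool, size=count, replace=False) if count else np.empty(0, int)
        taken.update(int(i) for i in chosen)
        return np.sort(chosen.astype(int))

    n_spike = round(spec.spike_rate * n)
    n_ratio = round(spec.ratio_outlier_rate * n)
    n_jump = round(spec.jump_rate * n)

    spikes = pick(effort_idx, n_spike)
    rr[spikes] = rng.uniform(1050.0, 1600.0, size=spikes.size)

    ratios = pick(np.arange(1, n - 1), n_ratio)
    up = rng.random(ratios.size) < 0.5
    factor = np.where(up, rng.uniform(2.5, 3.5, ratios.size), rng.uniform(0.25, 0.4, ratios.size))
    rr[ratios] = local_med[ratios] * factor

    jumps = pick(np.arange(1, n - 1), n_jump)
    delta = rng.uniform(12.0, 25.0, jumps.size) * inc_med[jumps]
    sign = np.where(rng.random(jumps.size) < 0.5, -1.0, 1.0)
    # keep the artifact a physical (positive) interval
    sign[rr[jumps] + sign * delta < 30.0] = 1.0
    rr[jumps] = rr[jumps] + sign * delta

    out = SubjectData(
        RRSeries(data.rr.t_s, rr, data.rr.phase),
        data.vo2_t_s, data.vo2, data.crf, data.truth, data.protocol, data.trend_ms,
        artifact_idx={"spike": spikes, "ratio": ratios, "jump": jumps},
    )
    return out


# ---------------------------------------------------------------------------
# cohort-level generation

#: cohort-level generator defaults; see docs/methods.md for the rationale
COHORT_DEFAULTS = dict(
    b_mean=1325.0,  # ms, ensemble HRV intercept
    b_logsd=0.10,  # lognormal spread of b_true
    b_loading=0.7,  # loading of log b_true on the fitness z-score
    tau_mean=19.6,  # beats/min, ensemble HRV halving constant
    tau_sd=0.45,  # inter-subject spread of tau_true
    vo2max_mean=37.0,  # mL/kg/min
    vo2max_sd=6.0,
    rr_rest_mean=700.0,  # ms (seated pre-test HR ~86; documented assumption)
    rr_rest_sd=40.0,
    rr_rest_fit_slope=25.0,  # ms per fitness z-score (fitter -> slower rest HR)
    ode_tau_mean=35.0,  # s
    ode_tau_sd=5.0,
    peak_hr_mean=187.0,  # beats/min
    peak_hr_sd=3.0,
)


def draw_cohort_truths(
    n_subjects: int,
    coupling: float = -0.75,
    seed=0,
    **overrides,
) -> list[SubjectTruth]:
    """Draw per-subject ground truths with a chosen tau-VO2max coupling.

    ``coupling`` is the generating correlation between tau_true and VO2max
    (Gaussian copula); at -1 tau_true is a strictly decreasing function of
    VO2max. b_true loads positively on fitness so fitter subjects have
    higher SDRR at low heart rate.
    """
    if n_subjects < 3:
        raise GenerationError("need at least 3 subjects (correlations undefined below)")
    if not -1.0 <= coupling <= 1.0:
        raise GenerationError("coupling must be in [-1, 1]")
    p = {**COHORT_DEFAULTS, **overrides}
    rng = np.random.default_rng(seed)

    truths = []
    for _ in range(n_subjects):
        z_fit = rng.standard_normal()
        vo2max = max(p["vo2max_mean"] + p["vo2max_sd"] * z_fit, 20.0)

        z_tau = coupling * z_fit + np.sqrt(1 - coupling**2) * rng.standard_normal()
        tau_true = max(p["tau_mean"] + p["tau_sd"] * z_tau, 5.0)

        z_b = p["b_loading"] * z_fit + np.sqrt(1 - p["b_loading"] ** 2) * rng.standard_normal()
        b_true = p["b_mean"] * np.exp(p["b_logsd"] * z_b)

        map_raw = 6.1 * vo2max + rng.normal(0.0, 35.0)
        map_w = 50.0 + 15.0 * max(round((map_raw - 50.0) / 15.0), 4)
        pvt1 = 0.47 * map_w * (1 + rng.normal(0.0, 0.08))
        pvt2 = 0.76 * map_w * (1 + rng.normal(0.0, 0.06))
        pvt2 = min(max(pvt2, pvt1 * 1.1), 0.95 * map_w)
        pvt1 = min(pvt1, 0.9 * pvt2)

        rr_rest = float(np.clip(
            p["rr_rest_mean"] + p["rr_rest_fit_slope"] * z_fit + rng.normal(0.0, p["rr_rest_sd"]),
            580.0, 900.0,
        ))
        ode_tau = float(np.clip(rng.normal(p["ode_tau_mean"], p["ode_tau_sd"]), 22.0, 55.0))
        peak_hr_target = rng.normal(p["peak_hr_mean"], p["peak_hr_sd"])
        # steady-state power deficit of the trend at the end of a completed
        # step of a staircase ramp: increment * e^(-h/tau) / (1 - e^(-h/tau))
        q = np.exp(-60.0 / ode_tau)
        lag_w = 15.0 * q / (1.0 - q)
        gain = (rr_rest - 60000.0 / peak_hr_target) / (map_w - lag_w)

        crf = CRFIndices(vo2max=vo2max, map_w=map_w, pvt1_w=pvt1, pvt2_w=pvt2)
        truths.append(SubjectTruth(
            rr_rest=rr_rest, ode_gain=gain, ode_tau=ode_tau, vo2_tau=0.7 * ode_tau,
            b_true=b_true, tau_true=tau_true, crf=crf, exhaustion_power=map_w,
        ))
    return truths


def simulate_cohort(
    n_subjects: int = 18,
    coupling: float = -0.75,
    seed=0,
    artifacts: ArtifactSpec | None = None,
    **truth_overrides,
) -> list[SubjectData]:
    """Simulate a full cohort of graded exercise tests.

    Every per-subject seed derives from the master seed, so a run is fully
    reproducible. If ``artifacts`` is given, its rates are applied to every
    subject (with per-subject derived seeds); pass ``ArtifactSpec()`` for
    the calibration rates.
    """
    ss = np.random.SeedSequence(seed)
    truth_seed, *subj_seeds = ss.spawn(2 * n_subjects + 1)
    truths = draw_cohort_truths(n_subjects, coupling, truth_seed, **truth_overrides)

    cohort = []
    for i, truth in enumerate(truths):
        protocol = make_protocol(exhaustion_power_w=truth.exhaustion_power)
        data = simulate_subject(protocol, truth, subj_seeds[2 * i])
        if artifacts is not None:
            art_seed = int(subj_seeds[2 * i + 1].generate_state(1)[0] % (2**31))
            data = inject_artifacts(data, replace(artifacts, seed=art_seed))
        cohort.append(data)
    return cohort
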