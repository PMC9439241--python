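"""Cohort-level statistics: per-subject decay fits, correlations with
cardiorespiratory fitness, heart-rate recovery, and the detrending
sensitivity grid.

The central question these routines serve: does the per-subject HRV decay
constant (tau of the HR-based decay model) track fitness? Correlations are
reported both as Pearson product-moment r (with a two-sided t-test) and as
rank correlation — Pearson applied to midranks, i.e. Spearman's rho. No
multiple-testing correction is applied; p-values are reported raw.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .decay import DecayFit, FitError, fit_decay
from .detrend import PolyDetrendConfig
from .process import process_subject
from .synthetic import SubjectData

CRF_INDEX_NAMES = ("vo2max", "map", "pvt1", "pvt2", "peak_hr", "hrr")


class CohortError(ValueError):
    pass


def pearson_linear(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise CohortError("need matched samples of size >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise CohortError("non-finite values in correlation input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise CohortError("correlation undefined for zero-variance input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def pearson_rank(x, y) -> tuple[float, float]:
    """Rank correlation: Pearson applied to midranks (ties averaged)."""
    return pearson_linear(stats.rankdata(x), stats.rankdata(y))


def compute_hrr(t_s, hr_bpm, exercise_end_s: float, smooth_beats: int = 5) -> float:
    """60 s heart-rate recovery from a beat-wise HR series.

    Peak HR (maximum ``smooth_beats``-beat rolling mean before exercise
    cessation) minus the rolling-mean HR at 60 s after cessation.
    """
    t = np.asarray(t_s, dtype=float)
    hr = np.asarray(hr_bpm, dtype=float)
    if t[-1] < exercise_end_s + 60.0:
        raise CohortError("need at least 60 s of recovery data")
    sm = pd.Series(hr).rolling(smooth_beats, center=True, min_periods=1).mean().to_numpy()
    before = sm[t <= exercise_end_s]
    if before.size == 0:
        raise CohortError("no beats before exercise cessation")
    peak = float(before.max())
    i60 = int(np.argmin(np.abs(t - (exercise_end_s + 60.0))))
    return peak - float(sm[i60])


def fit_cohort(
    cohort: list[SubjectData],
    clean: bool = True,
    effort_range: str = "full",
) -> tuple[list[DecayFit | None], list[pd.DataFrame]]:
    """Per-subject HR-decay (model 1) fits over each subject's windows.

    Non-converging subjects are flagged with None and excluded from
    downstream correlations with a warning. Raises if fewer than 3 fits
    converge. Returns (fits, per-subject window tables).
    """
    fits: list[DecayFit | None] = []
    tables: list[pd.DataFrame] = []
    for i, data in enumerate(cohort):
        table, _, _ = process_subject(data, clean=clean)
        tables.append(table)
        try:
            fits.append(fit_decay(table, model=1, effort_range=effort_range))
        except FitError as err:
            warnings.warn(f"subject {i}: decay fit failed ({err}); excluded", stacklevel=2)
            fits.append(None)
    if sum(f is not None for f in fits) < 3:
        raise CohortError("fewer than 3 subjects with converged fits")
    return fits, tables


def crf_table(cohort: list[SubjectData]) -> pd.DataFrame:
    """Per-subject fitness indices as a DataFrame (one row per subject)."""
    rows = []
    for data in cohort:
        c = data.crf
        rows.append({"vo2max": c.vo2max, "map": c.map_w, "pvt1": c.pvt1_w,
                     "pvt2": c.pvt2_w, "peak_hr": c.peak_hr, "hrr": c.hrr})
    return pd.DataFrame(rows)


def correlate_crf(
    fits: list[DecayFit | None],
    crf: pd.DataFrame,
    method: str = "linear",
) -> pd.DataFrame:
    """Correlation table of the fitted decay coefficients vs fitness indices.

    One row per (coefficient in {tau_hr, b_hr}, index in {vo2max, map,
    pvt1, pvt2, peak_hr, hrr}); columns r, p_value, method, n.
    """
    if len(fits) != len(crf):
        raise CohortError("fits and CRF table must have matched subjects")
    corr = {"linear": pearson_linear, "rank": pearson_rank}.get(method)
    if corr is None:
        raise CohortError(f"unknown method {method!r}")
    keep = [i for i, f in enumerate(fits) if f is not None]
    tau = np.array([fits[i].tau for i in keep])
    b = np.array([fits[i].b for i in keep])
    rows = []
    for coef_name, values in (("tau_hr", tau), ("b_hr", b)):
        for index in CRF_INDEX_NAMES:
            xi = crf[index].to_numpy(dtype=float)[keep]
            r, p = corr(values, xi)
            rows.append({"coefficient": coef_name, "index": index,
                         "r": r, "p_value": p, "method": method, "n": len(keep)})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SensitivityCell:
    p: int
    omega: int
    r: float
    p_value: float
    significant: bool
    n_subjects: int
    missing: bool = False


def sensitivity_grid(
    cohort: list[SubjectData],
    orders=(0, 1, 2),
    omegas=None,
    index: str = "vo2max",
    clean: bool = True,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Robustness grid over the local-polynomial detrending parameters.

    For every (polynomial order p, window size omega): detrend each
    subject's RR series with the order-p, omega-beat local polynomial,
    compute SDRR in count-mode windows of the same omega, fit the HR decay
    model per subject, and correlate the fitted decay constants with the
    chosen fitness index. Default grid: p in {0, 1, 2} x odd omega in
    [5, 101] = 147 cells. Cells with fewer than 3 converged subjects are
    flagged missing rather than failing the grid.
    """
    if omegas is None:
        omegas = range(5, 102, 2)
    omegas = list(omegas)
    # cleaning does not depend on (p, omega): do it once per subject
    from .preprocess import clean_rr

    cleaned = []
    for data in cohort:
        rr = clean_rr(data.rr)[0] if clean else data.rr
        cleaned.append(rr)

    rows = []
    for p in orders:
        for omega in omegas:
            taus, xis = [], []
            for data, rr in zip(cohort, cleaned):
                try:
                    from .detrend import detrend_poly
                    from .windows import windowed_hrv

                    x_det = detrend_poly(rr.rr_ms, PolyDetrendConfig(p, omega))
                    table = windowed_hrv(rr, x_det, mode="count", omega=omega,
                                         protocol=data.protocol)
                    fit = fit_decay(table, model=1, effort_range="full")
                except (FitError, ValueError):
                    continue
                taus.append(fit.tau)
                xis.append(data.crf.__getattribute__(
                    {"vo2max": "vo2max", "map": "map_w", "pvt1": "pvt1_w",
                     "pvt2": "pvt2_w", "peak_hr": "peak_hr", "hrr": "hrr"}[index]))
            if len(taus) >= 3:
                r, pv = pearson_linear(taus, xis)
                rows.append({"p": p, "omega": omega, "r": r, "p_value": pv,
                             "significant": pv < alpha, "n_subjects": len(taus),
                             "missing": False})
            else:
                rows.append({"p": p, "omega": omega, "r": np.nan, "p_value": np.nan,
                             "significant": False, "n_subjects": len(taus),
                             "missing": True})
    return pd.DataFrame(rows)
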