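"""Windowed SDRR and aligned covariates.

HRV is quantified as the sample standard deviation of the *detrended* RR
intervals (SDRR) in successive non-overlapping windows, with the mean heart
rate, mean workload and mean work intensity (% of VO2max) computed in the
same windows. Two windowing modes exist:

* ``time`` mode: successive 60 s windows aligned to the start of each phase
  span (rest, effort, recovery), so effort windows coincide with the 1 min
  power steps of the protocol;
* ``count`` mode: k = floor(n / omega) full windows of omega beats, the
  trailing n - k*omega beats discarded (used by the sensitivity analysis,
  with the same omega as the polynomial detrender).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import RRSeries, rr_to_hr
from .protocol import GETProtocol


class WindowError(ValueError):
    pass


@dataclass(frozen=True)
class WindowSpec:
    """Half-open beat-index window [lo, hi) with its time bounds and phase."""

    lo: int
    hi: int
    t_start: float
    t_end: float
    phase: str

    @property
    def n_beats(self) -> int:
        return self.hi - self.lo


def window_series(
    rr: RRSeries,
    mode: str = "time",
    omega: int | None = None,
    window_s: float = 60.0,
    min_beats: int = 3,
) -> list[WindowSpec]:
    """Partition a beat series into successive non-overlapping windows."""
    n = len(rr)
    if n == 0:
        raise WindowError("empty series")
    if mode == "count":
        if omega is None or omega < 1:
            raise WindowError("count mode needs omega >= 1")
        if omega > n:
            raise WindowError(f"omega {omega} exceeds series length {n}")
        k = n // omega
        out = []
        for j in range(k):
            lo, hi = j * omega, (j + 1) * omega
            phase = _majority_phase(rr.phase[lo:hi])
            out.append(WindowSpec(lo, hi, float(rr.t_s[lo]), float(rr.t_s[hi - 1]), phase))
        return out
    if mode != "time":
        raise WindowError(f"unknown mode {mode!r}")

    out = []
    for phase, lo_i, hi_i in _phase_spans(rr.phase):
        t0, t1 = rr.t_s[lo_i], rr.t_s[hi_i - 1]
        start = t0
        while start < t1 + 1e-9:
            end = start + window_s
            sel = np.flatnonzero((rr.t_s >= start - 1e-9) & (rr.t_s < end - 1e-9))
            sel = sel[(sel >= lo_i) & (sel < hi_i)]
            if sel.size >= min_beats:
                out.append(WindowSpec(int(sel[0]), int(sel[-1]) + 1,
                                      float(start), float(end), phase))
            start = end
    return out


def _phase_spans(phase: np.ndarray) -> list[tuple[str, int, int]]:
    spans = []
    lo = 0
    for i in range(1, phase.size + 1):
        if i == phase.size or phase[i] != phase[lo]:
            spans.append((str(phase[lo]), lo, i))
            lo = i
    return spans


def _majority_phase(phase: np.ndarray) -> str:
    vals, counts = np.unique(phase, return_counts=True)
    return str(vals[np.argmax(counts)])


def compute_sdrr(x_det, windows: list[WindowSpec]) -> np.ndarray:
    """Sample standard deviation (n-1 denominator) of x_det per window.

    Windows with fewer than 2 beats yield NaN (excluded downstream).
    """
    x = np.asarray(x_det, dtype=float)
    out = np.empty(len(windows))
    for j, w in enumerate(windows):
        seg = x[w.lo:w.hi]
        out[j] = np.std(seg, ddof=1) if seg.size >= 2 else np.nan
    return out


def window_covariates(
    rr: RRSeries,
    windows: list[WindowSpec],
    protocol: GETProtocol | None = None,
    vo2_t_s=None,
    vo2=None,
    vo2max: float | None = None,
):
    """Mean HR, mean power and mean work intensity aligned to the windows.

    HR is averaged over the *raw* beats in the window (detrended values can
    be negative, so HR is never derived from them); power is the time
    average of the protocol's P(t) over the window's span; work intensity is
    100 * mean(VO2) / VO2max (NaN when no VO2 series is given).
    """
    hr = np.empty(len(windows))
    p = np.full(len(windows), np.nan)
    i_pct = np.full(len(windows), np.nan)
    for j, w in enumerate(windows):
        hr[j] = float(np.mean(rr_to_hr(rr.rr_ms[w.lo:w.hi])))
        if protocol is not None:
            p[j] = protocol.mean_power(w.t_start, w.t_end)
        if vo2 is not None:
            if vo2max is None:
                raise WindowError(f"window {j}: VO2 series given without vo2max")
            sel = (np.asarray(vo2_t_s) >= w.t_start) & (np.asarray(vo2_t_s) < w.t_end)
            if not np.any(sel):
                raise WindowError(f"window {j}: no VO2 coverage in [{w.t_start}, {w.t_end})")
            i_pct[j] = 100.0 * float(np.mean(np.asarray(vo2)[sel])) / vo2max
    return hr, p, i_pct


def windowed_hrv(
    rr: RRSeries,
    x_det,
    mode: str = "time",
    omega: int | None = None,
    protocol: GETProtocol | None = None,
    vo2_t_s=None,
    vo2=None,
    vo2max: float | None = None,
) -> pd.DataFrame:
    """Full per-window HRV table: SDRR plus aligned covariates.

    Columns: j, phase, t_start, t_end, n_beats, sdrr_ms, hr_bpm, p_w, i_pct.
    """
    windows = window_series(rr, mode=mode, omega=omega)
    sdrr = compute_sdrr(x_det, windows)
    hr, p, i_pct = window_covariates(rr, windows, protocol, vo2_t_s, vo2, vo2max)
    return pd.DataFrame({
        "j": np.arange(len(windows)),
        "phase": [w.phase for w in windows],
        "t_start": [w.t_start for w in windows],
        "t_end": [w.t_end for w in windows],
        "n_beats": [w.n_beats for w in windows],
        "sdrr_ms": sdrr,
        "hr_bpm": hr,
        "p_w": p,
        "i_pct": i_pct,
    })
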