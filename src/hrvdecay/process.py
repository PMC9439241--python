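"""Per-subject processing: clean -> detrend -> windowed HRV table."""

from __future__ import annotations

import pandas as pd

from .detrend import PolyDetrendConfig, TrendFit, detrend_ode, detrend_poly
from .preprocess import CleanReport, clean_rr
from .synthetic import SubjectData
from .windows import windowed_hrv


def process_subject(
    data: SubjectData,
    clean: bool = True,
    method: str = "ode",
    poly_cfg: PolyDetrendConfig | None = None,
    window_mode: str = "time",
    omega: int | None = None,
) -> tuple[pd.DataFrame, TrendFit | None, CleanReport | None]:
    """Run one subject through cleaning, detrending and windowing.

    ``method`` selects the ODE detrender (main pipeline, 60 s time windows)
    or the local polynomial detrender (sensitivity analysis, count windows
    of the same omega). Returns (window table, trend fit or None, clean
    report or None).
    """
    rr = data.rr
    report = None
    if clean:
        rr, report = clean_rr(rr)

    if method == "ode":
        x_det, fit = detrend_ode(rr, data.protocol.power_at)
    elif method == "poly":
        if poly_cfg is None:
            raise ValueError("poly method needs poly_cfg")
        x_det, fit = detrend_poly(rr.rr_ms, poly_cfg), None
        if window_mode == "count" and omega is None:
            omega = poly_cfg.omega
    else:
        raise ValueError(f"unknown detrend method {method!r}")

    table = windowed_hrv(
        rr, x_det, mode=window_mode, omega=omega, protocol=data.protocol,
        vo2_t_s=data.vo2_t_s, vo2=data.vo2, vo2max=data.crf.vo2max,
    )
    return table, fit, report


def pooled_windows(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate per-subject window tables with a subject id column."""
    out = []
    for sid, tbl in enumerate(tables):
        t = tbl.copy()
        t.insert(0, "subject", sid)
        out.append(t)
    return pd.concat(out, ignore_index=True)
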