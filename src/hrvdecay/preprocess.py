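"""Beat-to-beat RR series: containers, RR<->HR conversion, artifact cleaning.

The cleaning procedure removes electrode-connection artifacts with three
sequential rules, each applied once in a forward pass over the survivors of
the previous rule:

1. RR intervals above 1000 ms during the effort phase are removed.
2. RR intervals exceeding twice, or below half, the median RR in a
   201-beat window centered on the beat are removed.
3. Beats whose absolute RR change from the previous surviving beat exceeds
   10 times the median absolute RR increment in a centered 201-beat window
   are removed.

Removed beats are deleted, never interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .protocol import PHASES


class RRSeriesError(ValueError):
    pass


def rr_to_hr(rr_ms):
    """Instantaneous heart rate (beats/min) from RR interval(s) in ms."""
    rr = np.asarray(rr_ms, dtype=float)
    if np.any(rr <= 0):
        raise ValueError("RR intervals must be positive")
    out = 60000.0 / rr
    return out if out.ndim else float(out)


def hr_to_rr(hr_bpm):
    """RR interval (ms) from heart rate(s) in beats/min; inverse of rr_to_hr."""
    hr = np.asarray(hr_bpm, dtype=float)
    if np.any(hr <= 0):
        raise ValueError("heart rate must be positive")
    out = 60000.0 / hr
    return out if out.ndim else float(out)


@dataclass
class RRSeries:
    """Timestamped RR interval series with phase labels.

    ``t_s[i]`` is the time of beat i (seconds from record start) and
    ``rr_ms[i]`` the RR interval ending at that beat. Phases must be
    contiguous in the order pre -> effort -> recovery (phases may be absent
    but never interleaved).
    """

    t_s: np.ndarray
    rr_ms: np.ndarray
    phase: np.ndarray

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.rr_ms = np.asarray(self.rr_ms, dtype=float)
        self.phase = np.asarray(self.phase, dtype="U8")
        if not (self.t_s.shape == self.rr_ms.shape == self.phase.shape):
            raise RRSeriesError("t_s, rr_ms and phase must have equal length")
        if self.t_s.size == 0:
            raise RRSeriesError("empty RR series")
        if np.any(self.rr_ms <= 0):
            raise RRSeriesError("RR intervals must be positive")
        if np.any(np.diff(self.t_s) <= 0):
            raise RRSeriesError("beat times must be strictly increasing")
        order = {p: i for i, p in enumerate(PHASES)}
        codes = np.array([order.get(p, -1) for p in self.phase])
        if np.any(codes < 0):
            raise RRSeriesError("unknown phase label")
        if np.any(np.diff(codes) < 0):
            raise RRSeriesError("phases must be contiguous pre -> effort -> recovery")

    def __len__(self) -> int:
        return self.t_s.size

    @property
    def hr_bpm(self) -> np.ndarray:
        return rr_to_hr(self.rr_ms)

    def take(self, idx) -> "RRSeries":
        return RRSeries(self.t_s[idx], self.rr_ms[idx], self.phase[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.t_s, "rr_ms": self.rr_ms, "phase": self.phase})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RRSeries":
        return cls(df["time_s"].to_numpy(), df["rr_ms"].to_numpy(), df["phase"].to_numpy())


@dataclass
class CleanReport:
    """Per-rule removal bookkeeping, indexed into the *input* series."""

    removed_rule1: np.ndarray
    removed_rule2: np.ndarray
    removed_rule3: np.ndarray
    n_input: int

    @property
    def n_removed(self) -> int:
        return len(self.removed_rule1) + len(self.removed_rule2) + len(self.removed_rule3)

    @property
    def fractions(self) -> dict[str, float]:
        n = self.n_input
        return {
            "rule1": len(self.removed_rule1) / n,
            "rule2": len(self.removed_rule2) / n,
            "rule3": len(self.removed_rule3) / n,
        }

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "removed_rule1": [int(i) for i in self.removed_rule1],
            "removed_rule2": [int(i) for i in self.removed_rule2],
            "removed_rule3": [int(i) for i in self.removed_rule3],
            "fractions": self.fractions,
        }


def _rolling_median(x: np.ndarray, window: int) -> np.ndarray:
    """Centered rolling median; windows clipped at the series boundaries."""
    return (
        pd.Series(x)
        .rolling(window=window, center=True, min_periods=1)
        .median()
        .to_numpy()
    )


def clean_rr(rr: RRSeries, median_window: int = 201) -> tuple[RRSeries, CleanReport]:
    """Apply the three artifact-removal rules and return survivors + report.

    Rules run in order 1 -> 2 -> 3, each on the survivors of the previous
    rule; window medians are computed on the survivor series entering the
    rule, with windows counted in beats and clipped at the boundaries.
    """
    if median_window % 2 == 0:
        raise ValueError("median_window must be odd")
    n0 = len(rr)
    orig = np.arange(n0)

    # rule 1: RR > 1000 ms during effort
    bad1 = (rr.rr_ms > 1000.0) & (rr.phase == "effort")
    removed1 = orig[bad1]
    keep = ~bad1
    x, idx = rr.rr_ms[keep], orig[keep]

    # rule 2: outside [0.5, 2] x local median
    if x.size:
        med = _rolling_median(x, median_window)
        bad2 = (x > 2.0 * med) | (x < 0.5 * med)
    else:
        bad2 = np.zeros(0, dtype=bool)
    removed2 = idx[bad2]
    x, idx = x[~bad2], idx[~bad2]

    # rule 3: |jump from previous surviving beat| > 10 x local median |increment|
    removed3_list: list[int] = []
    if x.size >= 2:
        med_inc = _rolling_median(np.abs(np.diff(x, prepend=x[0])), median_window)
        keep3 = np.ones(x.size, dtype=bool)
        last = 0
        for i in range(1, x.size):
            if abs(x[i] - x[last]) > 10.0 * med_inc[i]:
                keep3[i] = False
                removed3_list.append(int(idx[i]))
            else:
                last = i
        x, idx = x[keep3], idx[keep3]
    removed3 = np.array(removed3_list, dtype=int)

    if idx.size == 0:
        raise RRSeriesError("cleaning removed every beat; record unusable")

    cleaned = rr.take(idx)
    report = CleanReport(
        removed_rule1=np.asarray(removed1, dtype=int),
        removed_rule2=np.asarray(removed2, dtype=int),
        removed_rule3=removed3,
        n_input=n0,
    )
    return cleaned, report
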