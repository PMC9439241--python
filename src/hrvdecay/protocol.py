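"""Graded exercise test (GET) power protocols.

A GET is described as an ordered list of piecewise-constant power segments,
each labelled with an exercise phase: ``pre`` (seated rest), ``effort``
(cycling, stepwise incremental load) or ``recovery`` (seated rest after
exhaustion). The default protocol is 5 min rest, 3 min at 50 W, then
+15 W every minute until exhaustion, then 3 min of passive recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

PHASES = ("pre", "effort", "recovery")


class ProtocolError(ValueError):
    """Invalid protocol parameters."""


@dataclass(frozen=True)
class Segment:
    phase: str
    duration_s: float
    power_w: float


@dataclass(frozen=True)
class GETProtocol:
    """Piecewise-constant workload protocol of a graded exercise test."""

    segments: tuple[Segment, ...]
    step_duration_s: float = 60.0
    base_power_w: float = 50.0
    power_increment_w: float = 15.0

    def __post_init__(self) -> None:
        if not self.segments:
            raise ProtocolError("protocol needs at least one segment")
        for seg in self.segments:
            if seg.phase not in PHASES:
                raise ProtocolError(f"unknown phase {seg.phase!r}")
            if seg.duration_s <= 0:
                raise ProtocolError(f"non-positive duration in segment {seg}")
            if seg.power_w < 0:
                raise ProtocolError(f"negative power in segment {seg}")
            if seg.phase in ("pre", "recovery") and seg.power_w != 0:
                raise ProtocolError(f"{seg.phase} segment must be at 0 W")
        effort_p = [s.power_w for s in self.segments if s.phase == "effort"]
        if any(b < a for a, b in zip(effort_p, effort_p[1:])):
            raise ProtocolError("effort powers must be non-decreasing")

    @property
    def duration_s(self) -> float:
        return float(sum(s.duration_s for s in self.segments))

    @property
    def boundaries_s(self) -> np.ndarray:
        """Cumulative segment edges, length len(segments)+1, starting at 0."""
        return np.concatenate([[0.0], np.cumsum([s.duration_s for s in self.segments])])

    def power_at(self, t):
        """Power (W) at time ``t`` seconds from record start; vectorised.

        Segments are right-open: the power at a boundary is the power of the
        segment that starts there. Times past the end return the last power.
        """
        t = np.asarray(t, dtype=float)
        edges = self.boundaries_s
        idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, len(self.segments) - 1)
        powers = np.array([s.power_w for s in self.segments])
        out = powers[idx]
        return out if out.ndim else float(out)

    def phase_at(self, t):
        """Phase label at time ``t`` (vectorised, same edge convention)."""
        t = np.asarray(t, dtype=float)
        edges = self.boundaries_s
        idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, len(self.segments) - 1)
        phases = np.array([s.phase for s in self.segments])
        out = phases[idx]
        return out if out.ndim else str(out)

    def phase_spans(self) -> list[tuple[str, float, float]]:
        """Contiguous (phase, start_s, end_s) spans in protocol order."""
        spans: list[tuple[str, float, float]] = []
        edges = self.boundaries_s
        for i, seg in enumerate(self.segments):
            if spans and spans[-1][0] == seg.phase:
                spans[-1] = (seg.phase, spans[-1][1], float(edges[i + 1]))
            else:
                spans.append((seg.phase, float(edges[i]), float(edges[i + 1])))
        return spans

    def mean_power(self, t0: float, t1: float) -> float:
        """Time-average of the power over the interval [t0, t1]."""
        if t1 <= t0:
            raise ProtocolError("empty interval")
        edges = self.boundaries_s
        total = 0.0
        for i, seg in enumerate(self.segments):
            lo = max(t0, float(edges[i]))
            hi = min(t1, float(edges[i + 1]))
            if hi > lo:
                total += seg.power_w * (hi - lo)
        # time past the protocol end contributes the last segment's power
        if t1 > edges[-1]:
            total += self.segments[-1].power_w * (t1 - max(t0, float(edges[-1])))
        return total / (t1 - t0)


def make_protocol(
    rest_s: float = 300.0,
    base_power_w: float = 50.0,
    increment_w: float = 15.0,
    step_s: float = 60.0,
    recovery_s: float = 180.0,
    exhaustion_power_w: float = 230.0,
    base_duration_s: float = 180.0,
) -> GETProtocol:
    """Build a standard incremental GET protocol.

    ``exhaustion_power_w`` is the power of the last completed step (the
    maximal aerobic power). The effort block is a ``base_duration_s`` segment
    at ``base_power_w`` followed by ceil((exhaustion-base)/increment) steps of
    ``step_s`` seconds, each ``increment_w`` watts above the previous one.
    """
    for name, v in [("rest_s", rest_s), ("base_power_w", base_power_w),
                    ("increment_w", increment_w), ("step_s", step_s),
                    ("recovery_s", recovery_s), ("base_duration_s", base_duration_s)]:
        if v <= 0:
            raise ProtocolError(f"{name} must be positive, got {v}")
    if exhaustion_power_w < base_power_w:
        raise ProtocolError("exhaustion power below base power")

    segs = [Segment("pre", rest_s, 0.0), Segment("effort", base_duration_s, base_power_w)]
    n_steps = math.ceil((exhaustion_power_w - base_power_w) / increment_w)
    for k in range(1, n_steps + 1):
        segs.append(Segment("effort", step_s, base_power_w + k * increment_w))
    segs.append(Segment("recovery", recovery_s, 0.0))
    return GETProtocol(tuple(segs), step_duration_s=step_s,
                       base_power_w=base_power_w, power_increment_w=increment_w)
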