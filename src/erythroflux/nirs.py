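"""Reduction of 10 Hz muscle-oximetry (NIRS) traces.

A trace holds O2Hb and HHb (μM) from up to three optodes over three phases:
rest, exercise-or-occlusion, recovery. The reduction convention throughout is a
30-s trailing window: every reported value is the mean of the samples in the
30 s ending at its anchor time. Anchors are

* **baseline** — end of the rest phase (the "last 30 s of rest");
* **exercise bins** — the 10%, 20%, …, 100% points of the exercise duration,
  so traces of different exhaustion times always reduce to exactly 10 bins
  (windows are clipped at exercise start for very short durations);
* **occlusion minutes** — minutes 1–5 of the occlusion;
* **recovery** — 60, 90 and 120 s after the end of exercise/occlusion (cuff
  release).

Centered windows are available behind ``window_position="centered"``. Total
hemoglobin (tHb = O2Hb + HHb) commutes with every window mean, so summaries
report it as the sum of the two signal summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import DegenerateInputError, InvalidParameterError, ProtocolError
from .synthetic import NirsTrace

__all__ = [
    "NirsSummary",
    "optode_average",
    "baseline_value",
    "decile_bins",
    "recovery_values",
    "exercise_summary",
    "occlusion_summary",
]

WINDOW_S = 30.0
RECOVERY_ANCHORS_S = (60.0, 90.0, 120.0)
OCCLUSION_PROTOCOL_S = {"rest": 300.0, "work": 300.0, "recovery": 180.0}


def optode_average(trace: NirsTrace) -> NirsTrace:
    """Collapse a multi-optode trace to the pointwise mean across optodes."""
    if trace.n_optodes < 1:
        raise DegenerateInputError("trace has no optodes")
    return NirsTrace(
        time_s=trace.time_s,
        o2hb=trace.o2hb.mean(axis=0, keepdims=True),
        hhb=trace.hhb.mean(axis=0, keepdims=True),
        phase_marks=trace.phase_marks,
        meta=trace.meta,
    )


def _window_mean(trace: NirsTrace, signal: np.ndarray, anchor_s: float,
                 floor_s: float, position: str) -> float:
    """Mean of a 30-s window at ``anchor_s``, never extending before ``floor_s``."""
    if position == "trailing":
        lo, hi = anchor_s - WINDOW_S, anchor_s
    elif position == "centered":
        lo, hi = anchor_s - WINDOW_S / 2.0, anchor_s + WINDOW_S / 2.0
    else:
        raise InvalidParameterError(f"unknown window_position {position!r}")
    lo = max(lo, floor_s)
    # half-open (lo, hi]: a 30-s trailing window holds exactly 300 samples at 10 Hz
    mask = (trace.time_s > lo + 1e-9) & (trace.time_s <= hi + 1e-9)
    if not mask.any():
        raise DegenerateInputError(f"no samples in window ({lo}, {hi}] s")
    return float(signal[:, mask].mean())


def _per_signal(trace: NirsTrace, anchor_s, floor_s, position) -> dict[str, float]:
    o2 = _window_mean(trace, trace.o2hb, anchor_s, floor_s, position)
    hh = _window_mean(trace, trace.hhb, anchor_s, floor_s, position)
    return {"o2hb": o2, "hhb": hh, "thb": o2 + hh}


def baseline_value(trace: NirsTrace, window_position: str = "trailing") -> dict[str, float]:
    """Mean over the final 30 s of the rest phase, per signal (plus tHb)."""
    rest_start, rest_end = trace.phase_marks["rest"]
    if rest_end - rest_start < WINDOW_S:
        raise ProtocolError(
            f"rest phase of {rest_end - rest_start:.1f} s is shorter than the "
            f"{WINDOW_S:.0f} s baseline window"
        )
    # the baseline window is always trailing (the last 30 s of rest)
    return _per_signal(trace, rest_end, rest_start, "trailing")


def decile_bins(
    trace: NirsTrace, window_position: str = "trailing"
) -> dict[str, np.ndarray]:
    """Ten 30-s window means at 10%…100% of the exercise duration, per signal.

    Bin k is anchored at the k·10% time point of the work phase; the final bin
    ends at the last exercise sample. Windows never reach back before exercise
    start, so durations down to 60 s remain feasible (shorter raises an error).
    """
    work_start, work_end = trace.phase_marks["work"]
    duration = work_end - work_start
    if duration < 60.0:
        raise ProtocolError(
            f"exercise phase of {duration:.1f} s is too short to bin (< 60 s)"
        )
    out: dict[str, list[float]] = {"o2hb": [], "hhb": [], "thb": []}
    for k in range(1, 11):
        anchor = work_start + k * duration / 10.0
        vals = _per_signal(trace, anchor, work_start, window_position)
        for sig, v in vals.items():
            out[sig].append(v)
    return {sig: np.asarray(v) for sig, v in out.items()}


def recovery_values(
    trace: NirsTrace, window_position: str = "trailing"
) -> dict[str, np.ndarray]:
    """30-s window means at 60, 90 and 120 s after the end of exercise/occlusion."""
    work_end = trace.phase_marks["work"][1]
    rec_end = trace.phase_marks["recovery"][1]
    if rec_end - work_end < RECOVERY_ANCHORS_S[-1]:
        raise ProtocolError(
            f"recovery phase of {rec_end - work_end:.1f} s does not reach "
            f"{RECOVERY_ANCHORS_S[-1]:.0f} s"
        )
    out: dict[str, list[float]] = {"o2hb": [], "hhb": [], "thb": []}
    for dt in RECOVERY_ANCHORS_S:
        vals = _per_signal(trace, work_end + dt, work_end, window_position)
        for sig, v in vals.items():
            out[sig].append(v)
    return {sig: np.asarray(v) for sig, v in out.items()}


@dataclass(frozen=True)
class NirsSummary:
    """Reduced trace: baseline, 10 exercise bins or 5 occlusion minutes, recovery."""

    mode: str                                  # "exercise" | "occlusion"
    baseline: Mapping[str, float]
    bins: Mapping[str, np.ndarray]
    recovery: Mapping[str, np.ndarray]
    meta: Mapping[str, object] = field(default_factory=dict)

    @property
    def n_bins(self) -> int:
        return len(next(iter(self.bins.values())))


def exercise_summary(trace: NirsTrace, window_position: str = "trailing") -> NirsSummary:
    """Full incremental-exercise reduction: baseline, deciles, recovery."""
    avg = optode_average(trace)
    return NirsSummary(
        mode="exercise",
        baseline=baseline_value(avg),
        bins=decile_bins(avg, window_position),
        recovery=recovery_values(avg, window_position),
        meta=trace.meta,
    )


def occlusion_summary(
    trace: NirsTrace,
    window_position: str = "trailing",
    protocol_tolerance: float = 0.10,
) -> NirsSummary:
    """Vascular-occlusion reduction (5 min rest / 5 min occlusion / 3 min recovery).

    Phase lengths are checked against the protocol within a fractional
    ``protocol_tolerance``; minute-wise values are 30-s windows ending at
    minutes 1–5 of the occlusion.
    """
    for name, nominal in OCCLUSION_PROTOCOL_S.items():
        a, b = trace.phase_marks[name]
        if abs((b - a) - nominal) > protocol_tolerance * nominal:
            raise ProtocolError(
                f"{name} phase lasts {b - a:.1f} s; protocol expects "
                f"{nominal:.0f} s (±{100 * protocol_tolerance:.0f}%)"
            )
    avg = optode_average(trace)
    occ_start = avg.phase_marks["work"][0]
    out: dict[str, list[float]] = {"o2hb": [], "hhb": [], "thb": []}
    for minute in range(1, 6):
        vals = _per_signal(avg, occ_start + 60.0 * minute, occ_start, window_position)
        for sig, v in vals.items():
            out[sig].append(v)
    return NirsSummary(
        mode="occlusion",
        baseline=baseline_value(avg),
        bins={sig: np.asarray(v) for sig, v in out.items()},
        recovery=recovery_values(avg, window_position),
        meta=trace.meta,
    )
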