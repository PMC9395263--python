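"""Raw-trace preprocessing: filtering, turn conversion, event sorting.

Raw extension traces (nm, camera rate) are block-averaged down to the
analysis rate, converted into turns via a linear fit of the constant-torque
region of a hat curve, and cut into per-event windows (one per negative
applied-turns phase, where negative torque drives R-loop formation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trace import MagnetSchedule, TurnsTrace

__all__ = [
    "HatCurveFit",
    "decimate",
    "fit_hat_linear_region",
    "extension_to_turns",
    "segment_events",
]


@dataclass
class HatCurveFit:
    """Linear fit of the constant-torque branch of a hat curve."""

    slope: float
    intercept: float
    fit_window: tuple
    residual_sd: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope) or self.slope == 0:
            raise ValueError("slope must be finite and nonzero")


def decimate(trace: TurnsTrace, target_rate: float) -> TurnsTrace:
    """Boxcar decimation: non-overlapping block means.

    The decimation factor ``sample_rate / target_rate`` must be an
    integer; trailing samples that do not fill a block are dropped.  Block
    means keep step edges sharp, matching the display-style filtering of
    tweezers traces.  Ground-truth labels, if present, are carried over by
    block majority vote.
    """
    factor_f = trace.sample_rate / target_rate
    factor = int(round(factor_f))
    if factor < 1 or abs(factor_f - factor) > 1e-9:
        raise ValueError(
            f"sample_rate {trace.sample_rate} not an integer multiple of "
            f"target_rate {target_rate}")
    if factor == 1:
        return trace
    n_out = len(trace) // factor
    if n_out == 0:
        raise ValueError("trace shorter than one decimation block")
    sig = trace.signal[:n_out * factor].reshape(n_out, factor).mean(axis=1)
    time = trace.time[:n_out * factor].reshape(n_out, factor).mean(axis=1)
    truth = None
    if trace.truth_state is not None:
        blocks = trace.truth_state[:n_out * factor].reshape(n_out, factor)
        truth = np.array([np.bincount(b).argmax() for b in blocks])
    return TurnsTrace(time, sig, target_rate, trace.channel, truth)


def fit_hat_linear_region(extension, applied_turns, window) -> HatCurveFit:
    """OLS line through hat-curve points with applied turns inside ``window``.

    ``window`` is an inclusive ``(lo, hi)`` turn range selecting the
    constant-torque branch (negative turns for R-loop assays).
    """
    ext = np.asarray(extension, dtype=float)
    turns = np.asarray(applied_turns, dtype=float)
    if ext.shape != turns.shape:
        raise ValueError("extension and applied_turns must align")
    lo, hi = min(window), max(window)
    m = (turns >= lo) & (turns <= hi)
    if np.count_nonzero(m) < 3:
        raise ValueError("need at least 3 points inside the fit window")
    x, y = turns[m], ext[m]
    if np.ptp(x) == 0:
        raise ValueError("zero variance in applied turns inside the window")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    dof = max(x.size - 2, 1)
    return HatCurveFit(float(slope), float(intercept), (lo, hi),
                       float(np.sqrt(resid @ resid / dof)))


def extension_to_turns(trace: TurnsTrace, hat: HatCurveFit,
                       schedule: MagnetSchedule) -> TurnsTrace:
    """Convert an extension trace into turns of R-loop-induced unwinding.

    ``turns(t) = (extension(t) - intercept) / slope - applied(t)``.  With
    the negative-branch sign convention, R-loop formation under negative
    applied turns yields positive values (formation increases extension).
    """
    if trace.channel != "extension":
        raise ValueError("input trace must be an extension trace")
    if hat.slope == 0:
        raise ValueError("hat-curve slope is zero")
    turns = (trace.signal - hat.intercept) / hat.slope \
        - schedule.applied_at(trace.time)
    return TurnsTrace(trace.time, turns, trace.sample_rate, "turns",
                      trace.truth_state)


def segment_events(trace: TurnsTrace, schedule: MagnetSchedule,
                   settle_time: float = 0.2) -> list[tuple[float, float]]:
    """Per-event windows: one per negative-applied-turns phase.

    Each window starts ``settle_time`` after the rotation into the phase
    completes (excluding the unwinding transient) and ends at the next
    rotation command, clipped to the trace span.  Windows never overlap.
    """
    if not schedule.covers(trace.time[0], trace.time[-1]):
        raise ValueError("schedule does not cover the trace time span")
    t_lo = trace.time[0]
    t_hi = trace.time[-1] + 1.0 / trace.sample_rate
    windows = []
    n_seg = len(schedule.breakpoints)
    for i in range(n_seg):
        if schedule.applied_turns[i] >= 0:
            continue
        start = schedule.ramp_end(i) + settle_time
        end = schedule.breakpoints[i + 1] if i + 1 < n_seg else \
            (schedule.end_time if schedule.end_time is not None else t_hi)
        start = max(start, t_lo)
        end = min(end, t_hi)
        if end > start:
            windows.append((float(start), float(end)))
    return windows
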