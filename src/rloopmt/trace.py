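"""Core containers for magnetic-tweezers time series.

A tethered-bead experiment records apparent DNA extension versus time while
a magnet pair applies a programmed rotation schedule.  Everything downstream
(HMM state identification, clamp annotation) consumes these containers:

* :class:`TurnsTrace` -- a uniformly sampled trace, either raw extension in
  nm or a converted signal in turns of DNA linking difference.
* :class:`StatePath` -- a piecewise-constant state trajectory (dwell
  segments), used both as generator ground truth and as Viterbi output.
* :class:`MagnetSchedule` -- the applied-turns program, with finite-rate
  rotation ramps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TurnsTrace", "StatePath", "MagnetSchedule"]

#: relative tolerance on sampling uniformity
_UNIFORM_RTOL = 1e-6


@dataclass
class TurnsTrace:
    """Uniformly sampled bead signal.

    Parameters
    ----------
    time
        Sample times in seconds, uniformly spaced.
    signal
        Bead signal; nm if ``channel == "extension"``, turns otherwise.
    sample_rate
        Sampling rate in Hz.
    channel
        Either ``"extension"`` or ``"turns"``.
    truth_state
        Optional per-sample ground-truth state labels (generator output).
    """

    time: np.ndarray
    signal: np.ndarray
    sample_rate: float
    channel: str = "turns"
    truth_state: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.channel not in ("extension", "turns"):
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.time.shape != self.signal.shape or self.time.ndim != 1:
            raise ValueError("time and signal must be matching 1-D arrays")
        if self.time.size == 0:
            raise ValueError("empty trace")
        if not (np.all(np.isfinite(self.time)) and np.all(np.isfinite(self.signal))):
            raise ValueError("trace contains non-finite values")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.time.size > 1:
            dt = np.diff(self.time)
            nominal = 1.0 / self.sample_rate
            if np.any(np.abs(dt - nominal) > _UNIFORM_RTOL * nominal + 1e-12):
                raise ValueError("trace is not uniformly sampled at sample_rate")
        if self.truth_state is not None:
            self.truth_state = np.asarray(self.truth_state)
            if self.truth_state.shape != self.time.shape:
                raise ValueError("truth_state must match trace length")

    def __len__(self) -> int:
        return self.time.size

    @property
    def duration(self) -> float:
        """Span covered by the samples, in seconds (n / rate)."""
        return len(self) / self.sample_rate

    def window(self, t_start: float, t_end: float) -> "TurnsTrace":
        """Sub-trace with ``t_start <= time < t_end``."""
        m = (self.time >= t_start - 1e-12) & (self.time < t_end - 1e-12)
        if not np.any(m):
            raise ValueError(f"window [{t_start}, {t_end}) contains no samples")
        return TurnsTrace(
            self.time[m],
            self.signal[m],
            self.sample_rate,
            self.channel,
            None if self.truth_state is None else self.truth_state[m],
        )


@dataclass
class StatePath:
    """Piecewise-constant state trajectory as dwell segments.

    Segments tile ``[t_start[0], t_end[-1]]`` contiguously.  ``labels``
    optionally carries per-sample state indices for an associated trace
    (attached by the generator and by Viterbi decoding).
    """

    states: np.ndarray
    t_start: np.ndarray
    t_end: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=int)
        self.t_start = np.asarray(self.t_start, dtype=float)
        self.t_end = np.asarray(self.t_end, dtype=float)
        if not (self.states.shape == self.t_start.shape == self.t_end.shape):
            raise ValueError("states, t_start, t_end must have identical shapes")
        if self.states.size == 0:
            raise ValueError("empty state path")
        if np.any(self.t_end <= self.t_start):
            raise ValueError("segments must have positive duration")
        if np.any(np.abs(self.t_start[1:] - self.t_end[:-1]) > 1e-9):
            raise ValueError("segments must be contiguous")

    @property
    def duration(self) -> float:
        return float(self.t_end[-1] - self.t_start[0])

    @property
    def dwell_times(self) -> np.ndarray:
        return self.t_end - self.t_start

    def state_at(self, t: np.ndarray | float) -> np.ndarray:
        """State index at time(s) ``t`` (segments are left-closed)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.t_start, t, side="right") - 1
        idx = np.clip(idx, 0, len(self.states) - 1)
        return self.states[idx]

    def total_time_in(self, state: int, t0: float | None = None,
                      t1: float | None = None) -> float:
        """Total dwell time in ``state`` clipped to ``[t0, t1]``."""
        t0 = self.t_start[0] if t0 is None else t0
        t1 = self.t_end[-1] if t1 is None else t1
        lo = np.maximum(self.t_start, t0)
        hi = np.minimum(self.t_end, t1)
        ov = np.clip(hi - lo, 0.0, None)
        return float(ov[self.states == state].sum())

    @classmethod
    def from_labels(cls, labels: np.ndarray, time: np.ndarray,
                    sample_rate: float) -> "StatePath":
        """Run-length encode per-sample labels into dwell segments."""
        labels = np.asarray(labels)
        change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [labels.size]])
        dt = 1.0 / sample_rate
        return cls(
            states=labels[starts],
            t_start=time[starts],
            t_end=time[ends - 1] + dt,
            labels=labels,
        )


@dataclass
class MagnetSchedule:
    """Applied magnet-rotation program.

    ``applied_turns[i]`` is the target linking difference for the segment
    beginning at ``breakpoints[i]``; the magnets rotate to the new target at
    ``rotation_rate`` turns/s, so each segment starts with a linear ramp.
    The first segment starts already at its target (no initial ramp).
    """

    breakpoints: np.ndarray
    applied_turns: np.ndarray
    rotation_rate: float = 10.0
    force: float = 0.3
    end_time: float | None = None

    def __post_init__(self) -> None:
        self.breakpoints = np.asarray(self.breakpoints, dtype=float)
        self.applied_turns = np.asarray(self.applied_turns, dtype=float)
        if self.breakpoints.shape != self.applied_turns.shape:
            raise ValueError("breakpoints and applied_turns must align")
        if self.breakpoints.size == 0:
            raise ValueError("empty schedule")
        if np.any(np.diff(self.breakpoints) <= 0):
            raise ValueError("breakpoints must be strictly increasing")
        if self.rotation_rate <= 0:
            raise ValueError("rotation_rate must be positive")

    def covers(self, t0: float, t1: float) -> bool:
        if t0 < self.breakpoints[0] - 1e-9:
            return False
        return self.end_time is None or t1 <= self.end_time + 1e-9

    def ramp_end(self, i: int) -> float:
        """Time at which the rotation into segment ``i`` completes."""
        if i == 0:
            return float(self.breakpoints[0])
        delta = abs(self.applied_turns[i] - self.applied_turns[i - 1])
        return float(self.breakpoints[i] + delta / self.rotation_rate)

    def applied_at(self, t: np.ndarray | float) -> np.ndarray:
        """Applied turns at time(s) ``t``, including rotation ramps."""
        scalar = np.ndim(t) == 0
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.empty_like(t)
        seg = np.clip(
            np.searchsorted(self.breakpoints, t, side="right") - 1,
            0, len(self.breakpoints) - 1,
        )
        for i in np.unique(seg):
            m = seg == i
            target = self.applied_turns[i]
            if i == 0:
                out[m] = target
                continue
            prev = self.applied_turns[i - 1]
            sign = np.sign(target - prev)
            ramped = prev + sign * self.rotation_rate * (t[m] - self.breakpoints[i])
            # clamp the ramp at the target
            out[m] = np.clip(ramped, min(prev, target), max(prev, target))
        return float(out[0]) if scalar else out
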