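"""Annotation of single-molecule cleavage traces and clamp statistics.

After Cas12a nicks the non-target strand, free rotation at the nick should
make the tether insensitive to magnet rotation.  In practice the enzyme can
clamp the downstream DNA, isolating the nick in a topological domain so
that rotation challenges trap supercoils (the DNA shortens).  Unstable
clamps release the trapped torque in 1-5 discrete steps; a stable clamp
persists through every remaining challenge until target-strand cleavage
breaks the tether (bead loss).

This module detects steps, classifies clamped/unclamped intervals against
the rotation schedule, and provides the comparison statistics (release-step
histogram, one-tailed two-proportion z-test) plus the cleavage-locus
overhang arithmetic.
"""

from __future__ import annotations

import numbers
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .trace import MagnetSchedule, TurnsTrace

__all__ = [
    "ClampInterval",
    "ClampAnnotation",
    "StepList",
    "detect_steps",
    "classify_clamp_intervals",
    "release_step_histogram",
    "overhang_length",
    "two_proportion_ztest",
]

INTERVAL_KINDS = ("unclamped", "clamped_unstable", "clamped_stable")


@dataclass
class ClampInterval:
    start: float
    end: float
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in INTERVAL_KINDS:
            raise ValueError(f"unknown interval kind {self.kind!r}")
        if self.end <= self.start:
            raise ValueError("interval must have positive duration")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class ClampAnnotation:
    """Event annotation of one cleavage trace.

    Intervals are ordered, non-overlapping and tile
    ``[nick_time, bead_loss_time]`` (or the trace end when censored).  At
    most one interval is ``clamped_stable`` and it is last.
    """

    nick_time: float | None
    intervals: list = field(default_factory=list)
    release_steps: list = field(default_factory=list)
    bead_loss_time: float | None = None
    torque_sign_at_dsb: str | None = None  # '+', '-', '0'
    censored: bool = False
    warning: str | None = None

    def validate(self) -> None:
        for iv in self.intervals:
            if not isinstance(iv, ClampInterval):
                raise TypeError("intervals must be ClampInterval")
        for a, b in zip(self.intervals, self.intervals[1:]):
            if b.start < a.end - 1e-9:
                raise ValueError("intervals overlap")
            if abs(b.start - a.end) > 1e-6:
                raise ValueError("intervals do not tile contiguously")
        stable = [i for i, iv in enumerate(self.intervals)
                  if iv.kind == "clamped_stable"]
        if len(stable) > 1:
            raise ValueError("more than one stable clamp interval")
        if stable and stable[0] != len(self.intervals) - 1:
            raise ValueError("stable clamp must be the last interval")
        for n in self.release_steps:
            if n not in (1, 2, 3, 4, 5):
                raise ValueError("release step counts must be in 1..5")

    @property
    def n_unstable(self) -> int:
        return sum(iv.kind == "clamped_unstable" for iv in self.intervals)

    @property
    def has_stable(self) -> bool:
        return any(iv.kind == "clamped_stable" for iv in self.intervals)

    def kind_at(self, t: float) -> str | None:
        for iv in self.intervals:
            if iv.start - 1e-9 <= t < iv.end:
                return iv.kind
        return None


@dataclass
class StepList:
    step_times: np.ndarray
    step_sizes: np.ndarray

    def __post_init__(self) -> None:
        self.step_times = np.asarray(self.step_times, dtype=float)
        self.step_sizes = np.asarray(self.step_sizes, dtype=float)
        if self.step_times.shape != self.step_sizes.shape:
            raise ValueError("step_times and step_sizes must align")

    def __len__(self) -> int:
        return self.step_times.size


def _noise_sd(x: np.ndarray) -> float:
    # robust noise estimate from first differences (steps are sparse)
    d = np.diff(x)
    if d.size == 0:
        return 0.0
    return float(1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0))


def detect_steps(trace: TurnsTrace, threshold: float | None = None,
                 min_dwell: float = 0.1) -> StepList:
    """Detect discrete steps by a two-sample sliding-window mean comparison.

    The statistic at sample ``i`` is the difference between the means of
    the ``w`` samples after and before ``i`` (``w = min_dwell * rate``).
    Contiguous regions where it exceeds ``threshold`` (default: 3x a robust
    noise sd) yield one step each, at the argmax of the statistic; steps of
    equal sign closer than ``min_dwell`` are merged.
    """
    x = trace.signal
    n = x.size
    rate = trace.sample_rate
    w = max(2, int(round(min_dwell * rate)))
    if n < 2 * w + 1:
        return StepList(np.empty(0), np.empty(0))
    if threshold is None:
        threshold = max(3.0 * _noise_sd(x), 1e-12)

    c = np.concatenate([[0.0], np.cumsum(x)])
    idx = np.arange(w, n - w + 1)
    score = (c[idx + w] - c[idx]) / w - (c[idx] - c[idx - w]) / w

    above = np.abs(score) >= threshold
    times, sizes = [], []
    i = 0
    while i < above.size:
        if not above[i]:
            i += 1
            continue
        j = i
        while j < above.size and above[j]:
            j += 1
        k = i + int(np.argmax(np.abs(score[i:j])))
        times.append(trace.time[idx[k]])
        sizes.append(score[k])
        i = j
    times = np.asarray(times)
    sizes = np.asarray(sizes)

    # merge same-sign steps separated by less than min_dwell
    keep_t, keep_s = [], []
    for t, s in zip(times, sizes):
        if keep_t and t - keep_t[-1] < min_dwell and np.sign(s) == np.sign(keep_s[-1]):
            keep_s[-1] += s
            continue
        keep_t.append(t)
        keep_s.append(s)
    return StepList(np.asarray(keep_t), np.asarray(keep_s))


def classify_clamp_intervals(trace: TurnsTrace, schedule: MagnetSchedule,
                             steps: StepList, full_level: float | None = None,
                             tol: float | None = None,
                             ended_by_bead_loss: bool = True) -> ClampAnnotation:
    """Annotate a cleavage trace with nick, clamp and release events.

    The signal convention is turns of unreleased supercoiling: 0 means the
    DNA is at full (relaxed) length and more negative values mean more
    trapped supercoils.  The nick is the first large upward step landing at
    full length; after it, any excursion below full length marks a clamped
    interval (a rotation challenge trapped supercoils), ended either by a
    stepwise release back to full length (unstable; release steps counted
    from ``steps``) or by bead loss (stable).
    """
    sig = trace.signal
    t = trace.time
    dt = 1.0 / trace.sample_rate
    if full_level is None:
        full_level = float(np.percentile(sig, 98))
    if tol is None:
        tol = max(4.0 * _noise_sd(sig), 1.0)

    end_time = float(t[-1] + dt)
    ann = ClampAnnotation(nick_time=None,
                          bead_loss_time=end_time if ended_by_bead_loss else None,
                          censored=not ended_by_bead_loss)

    # nick: first upward step whose post-step level reaches full length
    w = max(2, int(round(0.1 * trace.sample_rate)))
    nick = None
    for st, ss in zip(steps.step_times, steps.step_sizes):
        if ss <= 0:
            continue
        i = int(np.searchsorted(t, st))
        post = sig[i:i + w]
        pre = sig[max(0, i - w):i]
        if post.size and pre.size and \
                np.mean(post) >= full_level - tol and np.mean(pre) < full_level - tol:
            nick = float(st)
            break
    if nick is None:
        ann.warning = "no nick detected"
        return ann
    ann.nick_time = nick

    post_nick_bp = schedule.breakpoints[schedule.breakpoints > nick]
    if post_nick_bp.size == 0:
        ann.warning = "no rotation challenge after nick"
        ann.intervals = [ClampInterval(nick, end_time, "unclamped")]
        return ann

    below = (sig < full_level - tol) & (t >= nick)
    # contiguous below-full regions after the nick
    regions = []
    i = int(np.searchsorted(t, nick))
    m = below[i:]
    tt = t[i:]
    j = 0
    while j < m.size:
        if not m[j]:
            j += 1
            continue
        k = j
        while k < m.size and m[k]:
            k += 1
        regions.append((float(tt[j]), float(tt[k - 1] + dt)))
        j = k

    # drop sub-resolution blips
    regions = [r for r in regions if r[1] - r[0] >= 3 * dt]

    ramps = [(schedule.breakpoints[i], schedule.ramp_end(i))
             for i in range(1, len(schedule.breakpoints))]

    def in_ramp(t, pad=0.3):
        return any(b - pad <= t <= e + pad for b, e in ramps)

    def step_release_between(a, b):
        return bool(np.any((steps.step_times > a) & (steps.step_times < b)
                           & (steps.step_sizes > 0)
                           & np.array([not in_ramp(t, 0.1)
                                       for t in steps.step_times])))

    # A persistent clamp under alternating challenges relaxes whenever the
    # rotation unwinds the trapped supercoils and re-shortens at the next
    # challenge; such rotation-bounded gaps with no step release in between
    # belong to one continuing clamp episode.
    merged: list[list[float]] = []
    for r0, r1 in regions:
        if merged and in_ramp(merged[-1][1]) and in_ramp(r0) \
                and not step_release_between(merged[-1][1], r0):
            merged[-1][1] = r1
        else:
            merged.append([r0, r1])
    regions = [(a, b) for a, b in merged]

    intervals: list[ClampInterval] = []
    cursor = nick
    for q, (r0, r1) in enumerate(regions):
        last = q == len(regions) - 1
        stable = last and ended_by_bead_loss and (end_time - r1) <= 5 * dt
        if r0 > cursor + 1e-9:
            intervals.append(ClampInterval(cursor, r0, "unclamped"))
        if stable:
            intervals.append(ClampInterval(r0, end_time, "clamped_stable"))
            cursor = end_time
        else:
            intervals.append(ClampInterval(r0, r1, "clamped_unstable"))
            # a return to full length during a rotation ramp means the
            # rotation unwound the trapped supercoils (persistent clamp),
            # not a stepwise clamp release
            if not in_ramp(r1):
                n_rel = int(np.sum((steps.step_times > r0)
                                   & (steps.step_times <= r1 + 2 * dt)
                                   & (steps.step_sizes > 0)
                                   & ~np.array([in_ramp(t, 0.1)
                                                for t in steps.step_times])))
                ann.release_steps.append(int(np.clip(n_rel, 1, 5)))
            cursor = r1
    if cursor < end_time - 1e-9:
        intervals.append(ClampInterval(cursor, end_time, "unclamped"))
    ann.intervals = intervals

    if ended_by_bead_loss:
        if intervals and intervals[-1].kind == "clamped_stable":
            trapped = (schedule.applied_at(end_time)
                       - schedule.applied_at(intervals[-1].start))
            if abs(trapped) < 0.5:
                ann.torque_sign_at_dsb = "0"
            else:
                ann.torque_sign_at_dsb = "+" if trapped > 0 else "-"
        else:
            # free rotor at the moment of the double-strand break
            ann.torque_sign_at_dsb = "0"
    ann.validate()
    return ann


def release_step_histogram(annotations) -> tuple[np.ndarray, np.ndarray]:
    """Pooled histogram of release-step counts over 1..5 steps.

    Returns ``(counts, fractions)`` indexed by step count 1..5.
    """
    pooled = [n for ann in annotations for n in ann.release_steps]
    if not pooled:
        raise ValueError("no release events in the given annotations")
    counts = np.bincount(pooled, minlength=6)[1:6]
    return counts, counts / counts.sum()


def overhang_length(nts_pos, ts_pos) -> int:
    """5' overhang length from per-strand cleavage loci.

    Positions are 1-based, counted from the PAM-proximal end of the
    protospacer along each strand; the 5' overhang is ``ts_pos - nts_pos``.
    0 means a blunt cut and a negative value a 3' overhang.
    """
    for p in (nts_pos, ts_pos):
        if isinstance(p, numbers.Integral):
            continue
        if isinstance(p, numbers.Real) and float(p).is_integer():
            continue
        raise ValueError(f"cleavage position must be an integer, got {p!r}")
    length = int(ts_pos) - int(nts_pos)
    if length < 0:
        warnings.warn("negative overhang: 3' recessed (3' overhang) ends")
    return length


def two_proportion_ztest(x1: int, n1: int, x2: int, n2: int,
                         tail: str = "larger") -> tuple[float, float]:
    """One-tailed two-proportion z-test with pooled standard error.

    ``tail='larger'`` tests H1: p1 > p2 (upper-tail p value);
    ``tail='smaller'`` tests H1: p1 < p2.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("sample sizes must be >= 1")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("counts must satisfy 0 <= x <= n")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        raise ValueError("pooled proportion of 0 or 1: standard error undefined")
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (p1 - p2) / se
    if tail == "larger":
        p = float(stats.norm.sf(z))
    elif tail == "smaller":
        p = float(stats.norm.cdf(z))
    else:
        raise ValueError("tail must be 'larger' or 'smaller'")
    return float(z), p
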