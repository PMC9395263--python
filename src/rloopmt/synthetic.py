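"""Stochastic generators for every input the analysis pipeline consumes.

Three kinds of data are emulated, each with ground-truth labels so that
recovery can be tested:

* **R-loop formation traces** -- a continuous-time Markov chain hops among
  discrete turn-valued states (basal S0, intermediates, the full ~20-bp
  R-loop at 1.8 turns, and breathing states beyond it); the observed trace
  is the state position plus white Gaussian noise at the camera rate
  (60 Hz by default).  Extension rendering maps turns onto the linear
  branch of a hat curve, capped at the relaxed-DNA plateau.
* **Ensemble cleavage time courses** -- multinomial samples of SC/OC/LIN
  fractions from the closed-form two-step kinetic model.
* **Single-molecule cleavage (clamp) traces** -- the event grammar of
  post-nick clamping: R-loop formation, NTS nick (supercoil release),
  alternating unstable clamp episodes (rotation challenges trap supercoils;
  release back to full length in 1-5 discrete steps) and, eventually, a
  stable clamp that persists until TS cleavage breaks the tether.

All randomness flows through :func:`numpy.random.default_rng`; a fixed
seed reproduces every trace bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clamp import ClampAnnotation, ClampInterval
from .kinetics import CleavageTimecourse, model_fractions
from .trace import MagnetSchedule, StatePath, TurnsTrace

__all__ = [
    "SimParams",
    "ClampSimParams",
    "simulate_state_path",
    "emit_turns_trace",
    "render_extension",
    "simulate_timecourse",
    "simulate_clamp_trace",
    "simulate_clamp_events",
    "birth_death_rate_matrix",
    "wt_crrna24_params",
    "w355a_crrna24_params",
    "formation_schedule",
    "clamp_challenge_schedule",
]


# --------------------------------------------------------------------------
# parameters

@dataclass
class SimParams:
    """Generative model for R-loop formation traces.

    ``rate_matrix`` holds off-diagonal CTMC transition rates (per s);
    diagonals are ignored and recomputed as negative row sums.  State
    positions are in turns; ``emission_sd`` is the white-noise sd at the
    raw sampling rate.  The hat-curve parameters place the supercoiled
    linear branch (``extension = hat_intercept + hat_slope * turns``) and
    the relaxed-DNA plateau.
    """

    state_positions: np.ndarray
    rate_matrix: np.ndarray
    emission_sd: float = 0.12
    sample_rate: float = 60.0
    seed: int = 0
    hat_slope: float = 55.0
    hat_intercept: float = 600.0
    plateau_length: float = 600.0

    def __post_init__(self) -> None:
        self.state_positions = np.asarray(self.state_positions, dtype=float)
        self.rate_matrix = np.asarray(self.rate_matrix, dtype=float)
        k = self.state_positions.size
        if self.rate_matrix.shape != (k, k):
            raise ValueError("rate_matrix must be square, matching states")
        off = self.rate_matrix.copy()
        np.fill_diagonal(off, 0.0)
        if np.any(off < 0):
            raise ValueError("off-diagonal rates must be >= 0")
        if not np.all(np.isfinite(self.state_positions)):
            raise ValueError("state positions must be finite")
        if self.emission_sd <= 0:
            raise ValueError("emission_sd must be positive")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def n_states(self) -> int:
        return self.state_positions.size

    def generator_matrix(self) -> np.ndarray:
        """Full CTMC generator Q (diagonal = negative row sum)."""
        q = self.rate_matrix.copy()
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        return q

    def stationary_distribution(self) -> np.ndarray:
        q = self.generator_matrix()
        a = np.vstack([q.T, np.ones(self.n_states)])
        b = np.zeros(self.n_states + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(a, b, rcond=None)
        return np.clip(pi, 0.0, None) / np.clip(pi, 0.0, None).sum()


def birth_death_rate_matrix(occupancy, down_rate: float = 0.5) -> np.ndarray:
    """Nearest-neighbour rate matrix with a prescribed equilibrium.

    Downward rates (state i -> i-1) are all ``down_rate``; upward rates
    follow from detailed balance so the chain's stationary distribution
    equals ``occupancy``.
    """
    pi = np.asarray(occupancy, dtype=float)
    if np.any(pi <= 0) or abs(pi.sum() - 1.0) > 1e-9:
        raise ValueError("occupancy must be positive and sum to 1")
    k = pi.size
    q = np.zeros((k, k))
    for i in range(k - 1):
        q[i + 1, i] = down_rate
        q[i, i + 1] = down_rate * pi[i + 1] / pi[i]
    return q


def wt_crrna24_params(seed: int = 0, emission_sd: float = 0.12) -> SimParams:
    """Default WT-style six-state generator.

    S0 (basal) at 0, the full R-loop (main state) at the 1.8-turn
    calibration, the breathing state 0.2 turns beyond it (~2 bp), and three
    interpolated intermediates.  Only the 1.8-turn position is a measured
    calibration; the intermediates are placeholders, evenly spaced.
    The equilibrium puts most weight on the main state.
    """
    positions = np.array([0.0, 0.45, 0.9, 1.35, 1.8, 2.0])
    occupancy = np.array([0.04, 0.06, 0.10, 0.15, 0.55, 0.10])
    return SimParams(positions, birth_death_rate_matrix(occupancy, 0.5),
                     emission_sd=emission_sd, seed=seed)


def w355a_crrna24_params(seed: int = 0, emission_sd: float = 0.2) -> SimParams:
    """Mutant-style four-state generator: basal, intermediate, and the two
    extended states at 2.0 (dominant) and 2.3 turns.

    The mutant dwells longer in the extended states than WT (fewer
    transitions per event) and the emission noise matches the ~0.3-0.5
    turn FWHM scale of measured state peaks once filtered to 10 Hz.
    """
    positions = np.array([0.0, 1.35, 2.0, 2.3])
    occupancy = np.array([0.05, 0.15, 0.55, 0.25])
    return SimParams(positions, birth_death_rate_matrix(occupancy, 0.25),
                     emission_sd=emission_sd, seed=seed)


def formation_schedule(n_cycles: int = 1, neg_turns: float = -12.0,
                       pos_turns: float = 12.0, phase: float = 60.0,
                       rotation_rate: float = 10.0) -> MagnetSchedule:
    """Alternating negative/positive applied-turn cycles (formation /
    dissociation phases), starting on the negative phase."""
    bps, turns = [0.0], [neg_turns]
    t = phase
    for _ in range(n_cycles):
        bps.append(t)
        turns.append(pos_turns)
        t += phase
        if len(bps) // 2 < n_cycles:
            bps.append(t)
            turns.append(neg_turns)
            t += phase
    # always end the listed program after the final phase
    return MagnetSchedule(np.array(bps), np.array(turns),
                          rotation_rate=rotation_rate, end_time=t)


# --------------------------------------------------------------------------
# CTMC + emission

def simulate_state_path(params: SimParams, duration: float,
                        initial_state: int = 0,
                        rng: np.random.Generator | None = None) -> StatePath:
    """Gillespie realisation of the state CTMC over ``[0, duration]``.

    Dwell times in state i are exponential with rate ``-Q_ii``; an
    all-zero rate row is absorbing.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if not 0 <= initial_state < params.n_states:
        raise ValueError(f"invalid initial_state {initial_state}")
    rng = np.random.default_rng(params.seed) if rng is None else rng

    q = params.rate_matrix.copy()
    np.fill_diagonal(q, 0.0)
    exit_rates = q.sum(axis=1)

    states, starts = [], []
    t, s = 0.0, int(initial_state)
    while t < duration:
        states.append(s)
        starts.append(t)
        if exit_rates[s] == 0.0:
            break
        t += rng.exponential(1.0 / exit_rates[s])
        if t >= duration:
            break
        s = int(rng.choice(params.n_states, p=q[s] / exit_rates[s]))
    ends = starts[1:] + [duration]
    return StatePath(np.array(states), np.array(starts),
                     np.minimum(np.array(ends), duration))


def emit_turns_trace(path: StatePath, params: SimParams,
                     rng: np.random.Generator | None = None) -> TurnsTrace:
    """Sample the state path at ``sample_rate`` with Gaussian noise.

    Sample i is taken at ``t = i / rate`` (relative to the path start);
    ground-truth labels are retained on the trace.
    """
    rng = np.random.default_rng(params.seed) if rng is None else rng
    n = int(round(path.duration * params.sample_rate))
    if n == 0:
        raise ValueError("path too short for one sample")
    time = path.t_start[0] + np.arange(n) / params.sample_rate
    labels = path.state_at(time)
    signal = params.state_positions[labels] + rng.normal(
        0.0, params.emission_sd, size=n)
    return TurnsTrace(time, signal, params.sample_rate, "turns",
                      truth_state=labels)


def render_extension(trace: TurnsTrace, params: SimParams,
                     schedule: MagnetSchedule) -> TurnsTrace:
    """Map a turns trace to DNA extension on the hat-curve linear branch.

    ``extension = hat_intercept + hat_slope * (applied + rloop)`` while the
    effective linking difference is negative; once it reaches zero the DNA
    is relaxed and the extension caps at ``plateau_length``.
    """
    if trace.channel != "turns":
        raise ValueError("input trace must be in turns")
    if not schedule.covers(trace.time[0], trace.time[-1]):
        raise ValueError("schedule does not cover the trace time span")
    eff = schedule.applied_at(trace.time) + trace.signal
    ext = np.where(eff < 0.0,
                   params.hat_intercept + params.hat_slope * eff,
                   params.plateau_length)
    return TurnsTrace(trace.time, ext, trace.sample_rate, "extension",
                      truth_state=trace.truth_state)


# --------------------------------------------------------------------------
# ensemble cleavage time courses

def simulate_timecourse(k_nts: float, k_ts: float, f_active: float,
                        times, n_molecules: int, n_repeats: int = 1,
                        seed: int = 0) -> list[CleavageTimecourse]:
    """Multinomially sampled SC/OC/LIN time courses from the two-step model.

    At each time point, ``n_molecules`` plasmids are assigned to species
    with the closed-form probabilities; the inactive fraction stays SC.
    Each repeat is an independent draw.
    """
    if k_nts <= 0 or k_ts <= 0:
        raise ValueError("rate constants must be positive")
    if not 0 < f_active <= 1:
        raise ValueError("f_active must be in (0, 1]")
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    times = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    sc, oc, lin = model_fractions(k_nts, k_ts, f_active, times)
    probs = np.column_stack([sc, oc, lin])
    probs /= probs.sum(axis=1, keepdims=True)
    out = []
    for r in range(n_repeats):
        counts = np.vstack([rng.multinomial(n_molecules, p) for p in probs])
        out.append(CleavageTimecourse(times, counts / n_molecules,
                                      repeat_id=r, n_molecules=n_molecules))
    return out


# --------------------------------------------------------------------------
# clamp traces

@dataclass
class ClampSimParams:
    """Generative model for single-molecule cleavage (clamp) traces.

    Rates are per second: ``k_rloop`` (R-loop formation), ``k_nick`` (NTS
    nick from the R-loop), ``k_close``/``k_open`` (clamp closure/opening),
    ``k_ts_cut`` (TS cleavage from the stable clamp).  Each closure is
    irreversibly stable with probability ``p_stable``; unstable clamps
    release trapped torque in 1-5 discrete steps with probabilities
    ``n_release_steps_dist``.
    """

    k_nick: float = 0.25
    k_close: float = 1.0
    k_open: float = 1.2
    p_stable: float = 0.15
    k_ts_cut: float = 0.2
    n_release_steps_dist: tuple = (0.2, 0.2, 0.2, 0.2, 0.2)
    trapped_turns: float = 12.0
    k_rloop: float = 1.0
    rloop_turns: float = 1.8
    emission_sd: float = 0.3
    sample_rate: float = 60.0
    step_spacing: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("k_nick", "k_close", "k_open", "k_ts_cut", "k_rloop"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.p_stable <= 1:
            raise ValueError("p_stable must be in [0, 1]")
        d = np.asarray(self.n_release_steps_dist, dtype=float)
        if d.size != 5 or np.any(d < 0) or abs(d.sum() - 1.0) > 1e-9:
            raise ValueError("n_release_steps_dist must be 5 probabilities "
                             "over 1..5 steps summing to 1")


def clamp_challenge_schedule(first_challenge: float = 6.0,
                             period: float = 6.0, amplitude: float = 12.0,
                             n_challenges: int = 60,
                             rotation_rate: float = 10.0) -> MagnetSchedule:
    """Initial negative phase (R-loop formation) followed by alternating
    +/- rotation challenges every ``period`` seconds."""
    bps = [0.0] + [first_challenge + i * period for i in range(n_challenges)]
    turns = [-amplitude] + [amplitude * (1 if i % 2 == 0 else -1)
                            for i in range(n_challenges)]
    return MagnetSchedule(np.array(bps), np.array(turns),
                          rotation_rate=rotation_rate,
                          end_time=bps[-1] + period)


def _exp(rng: np.random.Generator, rate: float) -> float:
    return rng.exponential(1.0 / rate) if rate > 0 else np.inf


def simulate_clamp_events(params: ClampSimParams, schedule: MagnetSchedule,
                          rng: np.random.Generator | None = None):
    """Event-level realisation of one cleavage trace.

    Returns ``(segments, annotation)`` where ``segments`` is a list of
    ``(t0, t1, v0, v1)`` pieces (signal interpolates linearly from v0 to
    v1; the signal is turns of unreleased supercoiling, 0 = full length)
    and ``annotation`` is the ground truth.
    """
    rng = np.random.default_rng(params.seed) if rng is None else rng
    t_max = schedule.end_time
    if t_max is None:
        raise ValueError("clamp simulation needs a schedule with end_time")
    dt = 1.0 / params.sample_rate

    segments: list[tuple] = []

    def add_curve(t0, t1, level_fn, n_knots=32):
        """Append a (possibly kinked) analytic level as linear pieces
        broken at schedule ramp boundaries."""
        knots = [t0, t1]
        for i, b in enumerate(schedule.breakpoints):
            for tk in (b, schedule.ramp_end(i)):
                if t0 < tk < t1:
                    knots.append(tk)
            # |...| kinks where the effective linking difference crosses 0
        knots = sorted(set(knots))
        for a, b in zip(knots, knots[1:]):
            # subdivide ramps finely enough for the |.| kink
            m = max(2, int(np.ceil((b - a) / 0.05)))
            ts = np.linspace(a, b, m + 1)
            vs = level_fn(ts)
            for u0, u1, v0, v1 in zip(ts, ts[1:], vs, vs[1:]):
                segments.append((u0, u1, v0, v1))

    # --- pre-nick: intact supercoiled DNA -------------------------------
    t_rloop = _exp(rng, params.k_rloop)
    t_nick = t_rloop + _exp(rng, params.k_nick)
    t_nick = min(t_nick, t_max)  # censored before nick if beyond schedule
    add_curve(0.0, min(t_rloop, t_max),
              lambda ts: -np.abs(schedule.applied_at(ts)))
    nicked = t_nick < t_max and t_rloop < t_max
    if t_rloop < t_max:
        add_curve(t_rloop, t_nick,
                  lambda ts: -np.abs(schedule.applied_at(ts)
                                     + params.rloop_turns))
    ann = ClampAnnotation(nick_time=t_nick if nicked else None,
                          censored=not nicked)
    if not nicked:
        ann.warning = "censored before nick"
        return segments, ann

    # --- post-nick clamp state machine ----------------------------------
    intervals: list[ClampInterval] = []
    t = t_nick
    # a closure arriving within one camera frame of the nick traps the
    # pre-existing supercoils before they can release (no relaxed state)
    first_close_wait = _exp(rng, params.k_close)
    immediate = first_close_wait < dt
    bead_loss = None

    def release_staircase(t_open, trapped):
        """Stepwise release of ``trapped`` turns; returns (t_done, n_steps)."""
        n = 1 + int(rng.choice(5, p=np.asarray(params.n_release_steps_dist)))
        t_step = t_open
        level = trapped
        for j in range(n):
            gap = params.step_spacing * (0.6 + 0.8 * rng.random())
            t_next = t_step + gap
            segments.append((t_step, t_next, -abs(level), -abs(level)))
            level = trapped * (n - j - 1) / n
            t_step = t_next
        return t_step, n

    pending_close = first_close_wait
    trapped0 = (schedule.applied_at(t_nick) + params.rloop_turns) if immediate else 0.0
    while t < t_max:
        if immediate:
            t_close = t
            immediate = False
        else:
            t_close = t + pending_close
            if t_close >= t_max:
                segments.append((t, t_max, 0.0, 0.0))
                intervals.append(ClampInterval(t, t_max, "unclamped"))
                break
            # unclamped: free rotation, full length throughout
            segments.append((t, t_close, 0.0, 0.0))
            intervals.append(ClampInterval(t, t_close, "unclamped"))
            trapped0 = 0.0
        stable = rng.random() < params.p_stable
        a_close = schedule.applied_at(t_close)
        level_fn = lambda ts, a0=a_close, tr=trapped0: -np.abs(
            tr + schedule.applied_at(ts) - a0)
        if stable:
            t_cut = t_close + _exp(rng, params.k_ts_cut)
            if t_cut >= t_max:
                add_curve(t_close, t_max, level_fn)
                intervals.append(ClampInterval(t_close, t_max,
                                               "clamped_stable"))
                ann.censored = True
                break
            add_curve(t_close, t_cut, level_fn)
            intervals.append(ClampInterval(t_close, t_cut, "clamped_stable"))
            bead_loss = t_cut
            trapped = trapped0 + schedule.applied_at(t_cut) - a_close
            if abs(trapped) < 0.5:
                ann.torque_sign_at_dsb = "0"
            else:
                ann.torque_sign_at_dsb = "+" if trapped > 0 else "-"
            break
        t_open = t_close + _exp(rng, params.k_open)
        t_open = min(t_open, t_max)
        add_curve(t_close, t_open, level_fn)
        trapped = trapped0 + schedule.applied_at(t_open) - a_close
        if t_open >= t_max:
            intervals.append(ClampInterval(t_close, t_max, "clamped_unstable"))
            ann.censored = True
            break
        if abs(trapped) > 1e-9:
            t_done, n_steps = release_staircase(t_open, trapped)
            t_done = min(t_done, t_max)
            ann.release_steps.append(n_steps)
        else:
            t_done = t_open  # invisible episode: nothing was trapped
        intervals.append(ClampInterval(t_close, max(t_done, t_close + 1e-6),
                                       "clamped_unstable"))
        t = t_done
        pending_close = _exp(rng, params.k_close)

    ann.intervals = intervals
    ann.bead_loss_time = bead_loss
    if bead_loss is None:
        ann.censored = True
    ann.validate()
    return segments, ann


def _render_segments(segments, t_end, params: ClampSimParams,
                     rng: np.random.Generator) -> TurnsTrace:
    n = int(np.floor(t_end * params.sample_rate))
    time = np.arange(n) / params.sample_rate
    starts = np.array([s[0] for s in segments])
    signal = np.zeros(n)
    idx = np.clip(np.searchsorted(starts, time, side="right") - 1, 0,
                  len(segments) - 1)
    for i in range(len(segments)):
        m = idx == i
        if not np.any(m):
            continue
        t0, t1, v0, v1 = segments[i]
        if t1 > t0:
            frac = np.clip((time[m] - t0) / (t1 - t0), 0.0, 1.0)
        else:
            frac = 0.0
        signal[m] = v0 + (v1 - v0) * frac
    signal += rng.normal(0.0, params.emission_sd, size=n)
    return TurnsTrace(time, signal, params.sample_rate, "turns")


def simulate_clamp_trace(params: ClampSimParams, schedule: MagnetSchedule,
                         seed: int | None = None,
                         rng: np.random.Generator | None = None):
    """One rendered cleavage trace plus its ground-truth annotation.

    The trace ends at bead loss (TS cleavage) or, if censored, at the end
    of the rotation schedule.  Signal is in turns of unreleased
    supercoiling (0 = relaxed full length).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed if seed is None else seed)
    segments, ann = simulate_clamp_events(params, schedule, rng)
    t_end = ann.bead_loss_time if ann.bead_loss_time is not None else \
        schedule.end_time
    trace = _render_segments(segments, t_end, params, rng)
    return trace, ann
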