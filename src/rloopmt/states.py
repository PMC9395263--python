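"""HMM identification of discrete R-loop states and state statistics.

Each formation event is fitted with a Gaussian-emission hidden Markov
model; the Viterbi path assigns every sample a state, per-state histograms
are fitted with Gaussians to extract state positions, and the number of
states is chosen by the peak-separation rule: the largest state count whose
fitted positions are pairwise separated by more than ``min_separation``
turns (0.1 by default; tighter spacings merge the Gaussian peaks).

Occupancy P_r of a state is its total dwell time divided by the event
duration.  Turn values convert to base pairs through the R-loop
calibration: a full 20-bp R-loop changes the linking difference by
1.8 turns.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from hmmlearn.hmm import GaussianHMM
from lmfit.models import GaussianModel

from .trace import StatePath, TurnsTrace

__all__ = [
    "StateModel",
    "StatePeak",
    "EventRecord",
    "CalibrationConstant",
    "SelectionResult",
    "PopulationStateTable",
    "fit_gaussian_hmm",
    "viterbi_path",
    "gaussian_state_positions",
    "select_state_number",
    "event_statistics",
    "rupture_probability",
    "turns_to_bp",
    "box_stats",
    "aggregate_population",
]

FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548...

# EM restarts routinely stop on the iteration cap; that is expected here
logging.getLogger("hmmlearn.base").setLevel(logging.ERROR)


@dataclass
class StateModel:
    """Fitted Gaussian-emission HMM with states sorted by position."""

    n_states: int
    positions: np.ndarray
    emission_sd: np.ndarray
    transition_matrix: np.ndarray
    log_likelihood: float
    startprob: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.emission_sd = np.asarray(self.emission_sd, dtype=float)
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        if self.positions.size != self.n_states:
            raise ValueError("positions must have n_states entries")
        if np.any(np.diff(self.positions) < 0):
            raise ValueError("positions must be sorted ascending")
        if np.any(self.emission_sd <= 0):
            raise ValueError("emission_sd must be positive")
        rows = self.transition_matrix.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > 1e-9):
            raise ValueError("transition matrix rows must sum to 1")

    @property
    def basal_state(self) -> int:
        """Index of the state nearest 0 turns (R-loop dissociated)."""
        return int(np.argmin(np.abs(self.positions)))

    def to_hmmlearn(self) -> GaussianHMM:
        h = GaussianHMM(n_components=self.n_states, covariance_type="diag",
                        init_params="", min_covar=1e-10)
        h.startprob_ = (np.full(self.n_states, 1.0 / self.n_states)
                        if self.startprob is None else self.startprob)
        h.transmat_ = self.transition_matrix
        h.means_ = self.positions.reshape(-1, 1)
        h.covars_ = (self.emission_sd ** 2).reshape(-1, 1)
        return h


@dataclass
class StatePeak:
    """Gaussian fit of one state's turn-value histogram."""

    state: int
    position: float
    sd: float
    fwhm: float
    n_samples: int
    included: bool  # occupied enough to enter the selection rule


@dataclass
class SelectionResult:
    """Outcome of the peak-separation model-selection rule."""

    model: StateModel
    path: StatePath
    peaks: list
    accepted_k: int
    tried: dict = field(default_factory=dict)


@dataclass
class CalibrationConstant:
    """Turn <-> bp calibration: a full 20-bp R-loop = 1.8 turns."""

    turns_per_rloop: float = 1.8
    bp_per_rloop: float = 20.0

    def __post_init__(self) -> None:
        if self.turns_per_rloop <= 0 or self.bp_per_rloop <= 0:
            raise ValueError("calibration constants must be positive")


@dataclass
class EventRecord:
    """Per-event state statistics.

    ``occupancy`` (P_r) includes basal dwells in the normalisation;
    ``occupancy_rloop`` renormalises over R-loop states only (both
    conventions are reported).  ``rloop_size`` is the maximum fitted
    position among states dwelling at least ``min_dwell`` in the event;
    ``main_size`` is the position of the most-occupied non-basal state.
    """

    window: tuple
    occupancy: np.ndarray
    occupancy_rloop: np.ndarray
    positions: np.ndarray
    rloop_size: float
    main_size: float
    rupture_count: int
    state_count: int
    duration: float

    def __post_init__(self) -> None:
        if np.any(self.occupancy < -1e-12) or np.any(self.occupancy > 1 + 1e-12):
            raise ValueError("occupancies must lie in [0, 1]")
        if abs(self.occupancy.sum() - 1.0) > 1e-6:
            raise ValueError("occupancies must sum to 1")
        if self.rloop_size < 0:
            raise ValueError("rloop_size must be >= 0")


# --------------------------------------------------------------------------
# fitting

def _em_fit(x: np.ndarray, means0: np.ndarray, sd0: float, k: int,
            n_iter: int, tol: float) -> GaussianHMM:
    h = GaussianHMM(n_components=k, covariance_type="diag", n_iter=n_iter,
                    tol=tol, init_params="", params="stmc", min_covar=1e-10)
    h.startprob_ = np.full(k, 1.0 / k)
    h.transmat_ = np.full((k, k), 0.1 / max(k - 1, 1))
    np.fill_diagonal(h.transmat_, 0.9)
    h.means_ = means0.reshape(-1, 1)
    h.covars_ = np.full((k, 1), max(sd0, 1e-4) ** 2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        h.fit(x)
    return h


def _lloyd1d(x: np.ndarray, centers: np.ndarray, n_iter: int = 30) -> np.ndarray:
    """Refine 1-D cluster centers by Lloyd iterations."""
    centers = np.asarray(centers, dtype=float).copy()
    for _ in range(n_iter):
        assign = np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)
        new = centers.copy()
        for j in range(centers.size):
            m = assign == j
            if np.any(m):
                new[j] = x[m].mean()
        if np.allclose(new, centers, atol=1e-12):
            break
        centers = new
    return np.sort(centers)


def _kmeans1d(x: np.ndarray, k: int) -> np.ndarray:
    """Deterministic 1-D k-means (quantile-seeded Lloyd iterations)."""
    centers = np.quantile(x, (np.arange(k) + 0.5) / k)
    centers += np.arange(k) * 1e-9  # break exact ties
    return _lloyd1d(x, centers)


def _divisive_init(x: np.ndarray, k: int) -> np.ndarray:
    """Greedy divisive means: repeatedly split the cluster with the
    largest within-cluster SSE; separates close, heavy level pairs that
    plain k-means merges."""
    centers = np.array([x.mean()])
    while centers.size < k:
        assign = np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)
        sse = np.array([np.sum((x[assign == j] - centers[j]) ** 2)
                        for j in range(centers.size)])
        j = int(np.argmax(sse))
        xs = x[assign == j]
        spread = xs.std() if xs.size > 1 else max(x.std(), 1e-6)
        centers = np.sort(np.concatenate([
            np.delete(centers, j),
            [centers[j] - 0.7 * spread, centers[j] + 0.7 * spread]]))
        centers = _lloyd1d(x, centers, n_iter=10)
    return _lloyd1d(x, centers)


def fit_gaussian_hmm(trace: TurnsTrace, n_states: int, n_restarts: int = 5,
                     seed: int = 0, n_iter: int = 200,
                     tol: float = 1e-4) -> StateModel:
    """EM fit of a Gaussian-emission HMM; best of ``n_restarts`` restarts.

    Initial means are quantile-spaced over the signal; restarts perturb
    them with seeded Gaussian jitter, and the model with the highest
    log-likelihood wins.  Deterministic under a fixed seed.
    """
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    if len(trace) < 10 * n_states:
        raise ValueError("trace too short for the requested state count")
    x = trace.signal.reshape(-1, 1)
    span = float(np.ptp(trace.signal))
    if span == 0.0 and n_states > 1:
        raise ValueError("degenerate zero-variance trace with n_states > 1")
    if n_states == 1:
        mu = float(np.mean(trace.signal))
        sd = max(float(np.std(trace.signal)), 1e-9)
        ll = float(np.sum(-0.5 * ((trace.signal - mu) / sd) ** 2
                          - np.log(sd * np.sqrt(2 * np.pi))))
        return StateModel(1, np.array([mu]), np.array([sd]),
                          np.array([[1.0]]), ll, startprob=np.array([1.0]))

    rng = np.random.default_rng(seed)
    sd0 = float(np.std(trace.signal)) / n_states

    best, best_ll = None, -np.inf
    for r in range(n_restarts):
        # diversified initial means: divisive splits, k-means, quantiles,
        # then random data points
        if r == 0:
            means0 = _divisive_init(trace.signal, n_states)
        elif r == 1:
            means0 = _kmeans1d(trace.signal, n_states)
        elif r == 2:
            means0 = np.quantile(trace.signal,
                                 (np.arange(n_states) + 0.5) / n_states)
        else:
            means0 = np.sort(rng.choice(trace.signal, size=n_states,
                                        replace=False))
        try:
            h = _em_fit(x, means0, sd0, n_states, n_iter, tol)
            ll = float(h.score(x))
        except (ValueError, np.linalg.LinAlgError):
            continue
        if ll > best_ll:
            best, best_ll = h, ll
    if best is None:
        raise RuntimeError("all EM restarts failed")

    means = best.means_.ravel()
    order = np.argsort(means)
    sd = np.sqrt(best.covars_.reshape(best.n_components, -1).ravel())
    return StateModel(
        n_states,
        means[order],
        np.maximum(sd[order], 1e-12),
        best.transmat_[np.ix_(order, order)],
        best_ll,
        startprob=best.startprob_[order],
    )


def viterbi_path(model: StateModel, trace: TurnsTrace) -> StatePath:
    """Globally most probable state sequence (Viterbi decoding).

    The returned path carries per-sample labels and run-length-encoded
    dwell segments.
    """
    if model.n_states == 1:
        labels = np.zeros(len(trace), dtype=int)
    else:
        h = model.to_hmmlearn()
        _, labels = h.decode(trace.signal.reshape(-1, 1), algorithm="viterbi")
    return StatePath.from_labels(labels, trace.time, trace.sample_rate)


def gaussian_state_positions(model: StateModel, path: StatePath,
                             trace: TurnsTrace,
                             min_samples: int = 20) -> list[StatePeak]:
    """Per-state Gaussian fits of the assigned-sample histograms.

    States occupied by fewer than ``min_samples`` samples are flagged
    (``included=False``) and excluded from the model-selection rule.
    """
    if path.labels is None or path.labels.size != len(trace):
        raise ValueError("path must carry per-sample labels for this trace")
    peaks = []
    for s in range(model.n_states):
        samples = trace.signal[path.labels == s]
        n = samples.size
        if n == 0:
            peaks.append(StatePeak(s, float(model.positions[s]),
                                   float(model.emission_sd[s]),
                                   FWHM_FACTOR * float(model.emission_sd[s]),
                                   0, False))
            continue
        mu, sd = fit_gaussian_peak(samples)
        peaks.append(StatePeak(s, mu, sd, FWHM_FACTOR * sd, int(n),
                               n >= min_samples))
    return peaks


def fit_gaussian_peak(samples: np.ndarray) -> tuple[float, float]:
    """Gaussian fit of a sample histogram; returns (center, sd).

    Degenerate (near-constant) samples short-circuit to the sample mean.
    """
    samples = np.asarray(samples, dtype=float)
    mu0 = float(np.mean(samples))
    sd0 = float(np.std(samples))
    if sd0 < 1e-9 or samples.size < 10:
        return mu0, sd0
    nbins = max(10, min(80, samples.size // 10))
    counts, edges = np.histogram(samples, bins=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    gm = GaussianModel()
    pars = gm.make_params(center=mu0, sigma=sd0,
                          amplitude=samples.size * (edges[1] - edges[0]))
    pars["sigma"].set(min=1e-9)
    pars["center"].set(min=float(edges[0]), max=float(edges[-1]))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = gm.fit(counts, pars, x=centers)
        mu = float(out.params["center"].value)
        sd = abs(float(out.params["sigma"].value))
        # a fitted width beyond the sample span means the histogram has
        # no usable peak; report sample moments instead
        if not np.isfinite(mu) or sd > np.ptp(samples):
            return mu0, sd0
        return mu, sd
    except Exception:
        return mu0, sd0


def select_state_number(trace: TurnsTrace, k_max: int = 6,
                        min_separation: float = 0.1, n_restarts: int = 5,
                        seed: int = 0) -> SelectionResult:
    """Choose the state count by the peak-separation rule.

    Fits k = 1..k_max and returns the model with the largest k whose
    occupied Gaussian-fitted positions are pairwise separated by more
    than ``min_separation`` turns (adjacent pairs suffice for sorted
    positions).  k = 1 is always admissible.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    best = None
    tried = {}
    for k in range(1, k_max + 1):
        if len(trace) < 10 * k:
            break
        try:
            model = fit_gaussian_hmm(trace, k, n_restarts=n_restarts,
                                     seed=seed + 1000 * k)
        except (ValueError, RuntimeError):
            continue
        path = viterbi_path(model, trace)
        peaks = gaussian_state_positions(model, path, trace)
        pos = np.sort([p.position for p in peaks if p.included])
        admissible = pos.size <= 1 or np.all(np.diff(pos) > min_separation)
        tried[k] = (admissible, pos)
        if admissible:
            best = SelectionResult(model, path, peaks, accepted_k=k,
                                   tried=tried)
    if best is None:
        raise RuntimeError("no admissible model found")
    best.tried = tried
    return best


# --------------------------------------------------------------------------
# per-event and population statistics

def event_statistics(path: StatePath, model: StateModel,
                     window: tuple[float, float],
                     peaks: list[StatePeak] | None = None,
                     min_dwell: float = 0.5) -> EventRecord:
    """Occupancies, R-loop sizes and rupture count for one event window.

    P_r(state) is the dwell time in the state divided by the window
    duration.  The R-loop size is the maximum fitted position among
    states whose total dwell exceeds ``min_dwell`` (excluding transient
    single-sample excursions); the main size is the position of the
    most-occupied non-basal state.
    """
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("empty event window")
    duration = t1 - t0
    k = model.n_states
    positions = np.array([p.position for p in peaks]) if peaks is not None \
        else model.positions.copy()
    dwell = np.array([path.total_time_in(s, t0, t1) for s in range(k)])
    if dwell.sum() <= 0:
        raise ValueError("path does not cover the event window")
    occupancy = dwell / dwell.sum()

    basal = model.basal_state
    rl = np.ones(k, dtype=bool)
    rl[basal] = False
    occ_rl = np.zeros(k)
    if dwell[rl].sum() > 0:
        occ_rl[rl] = dwell[rl] / dwell[rl].sum()

    eligible = dwell >= min_dwell
    rloop_size = float(np.max(positions[eligible])) if np.any(eligible) \
        else float(positions[int(np.argmax(dwell))])
    rloop_size = max(rloop_size, 0.0)
    if np.any(rl & (dwell > 0)):
        main_idx = int(np.argmax(np.where(rl, dwell, -1.0)))
        main_size = float(positions[main_idx])
    else:
        main_size = 0.0

    in_win = (path.t_start < t1) & (path.t_end > t0)
    seq = path.states[in_win]
    ruptures = int(np.sum((seq[1:] == basal) & (seq[:-1] != basal)))
    return EventRecord((t0, t1), occupancy, occ_rl, positions, rloop_size,
                       max(main_size, 0.0), ruptures,
                       int(np.sum(dwell > 0)), duration)


def rupture_probability(path: StatePath, basal_state: int,
                        total_time: float) -> float:
    """Entries into the basal (dissociated) state per second of trace."""
    if total_time <= 0:
        raise ValueError("total_time must be positive")
    seq = path.states
    n = int(np.sum((seq[1:] == basal_state) & (seq[:-1] != basal_state)))
    return n / total_time


def turns_to_bp(x, cal: CalibrationConstant | None = None):
    """Convert turns to unwound base pairs via the R-loop calibration."""
    cal = cal or CalibrationConstant()
    return np.asarray(x, dtype=float) * cal.bp_per_rloop / cal.turns_per_rloop \
        if np.ndim(x) else float(x) * cal.bp_per_rloop / cal.turns_per_rloop


def box_stats(values) -> dict:
    """Box-plot statistics: median, IQR, 10/90% whiskers, mean
    (linear-interpolation quantiles)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty value set")
    q10, q25, q50, q75, q90 = np.percentile(v, [10, 25, 50, 75, 90])
    return {"median": float(q50), "q25": float(q25), "q75": float(q75),
            "iqr": float(q75 - q25), "whisker_lo": float(q10),
            "whisker_hi": float(q90), "mean": float(v.mean()),
            "n": int(v.size)}


@dataclass
class PopulationStateTable:
    """Pooled per-state statistics over many events."""

    table: pd.DataFrame
    rloop_size_stats: dict
    main_size_stats: dict
    n_events: int


def _cluster_positions(positions: np.ndarray, bandwidth: float) -> np.ndarray:
    """1-D mean-shift clustering of state positions.

    Each position ascends the kernel-density gradient to its local mode;
    positions sharing a mode share a cluster.  Unlike single-linkage this
    is robust to sparse 'bridge' positions between two heavy states (a
    handful of events whose fit landed between the true levels would
    otherwise chain the clusters together).
    """
    p = positions.astype(float)
    x = p.copy()
    for _ in range(200):
        w = np.exp(-0.5 * ((x[:, None] - p[None, :]) / bandwidth) ** 2)
        new = (w @ p) / w.sum(axis=1)
        if np.max(np.abs(new - x)) < 1e-10:
            x = new
            break
        x = new
    labels = np.full(p.size, -1, dtype=int)
    modes: list[float] = []
    for i in np.argsort(x):
        for c, m in enumerate(modes):
            if abs(x[i] - m) < bandwidth / 2:
                labels[i] = c
                break
        else:
            modes.append(x[i])
            labels[i] = len(modes) - 1
    return labels


def aggregate_population(events: list[EventRecord],
                         state_samples: list[dict] | None = None,
                         cluster_gap: float = 0.08) -> PopulationStateTable:
    """Pool per-event states into a population state table.

    Event states are matched across events by 1-D clustering of their
    fitted positions (split at gaps larger than ``cluster_gap`` turns).
    Pooled P_r is the event-duration-weighted mean occupancy; the pooled
    Gaussian peak is fitted over the concatenated per-state samples when
    ``state_samples`` (one dict ``state index -> sample array`` per event)
    is given.
    """
    if len(events) < 2:
        raise ValueError("need at least 2 events to aggregate")
    rows = []
    for e_idx, ev in enumerate(events):
        for s, pos in enumerate(ev.positions):
            if ev.occupancy[s] <= 0:
                continue
            rows.append((e_idx, s, pos, ev.occupancy[s], ev.duration))
    rows = pd.DataFrame(rows, columns=["event", "state", "position",
                                       "pr", "duration"])
    rows["cluster"] = _cluster_positions(rows["position"].to_numpy(),
                                         cluster_gap)

    total_dur = sum(ev.duration for ev in events)
    out = []
    for c, grp in rows.groupby("cluster"):
        pos = grp["position"].to_numpy()
        # duration-weighted pooled P_r over ALL events (absent -> 0)
        pooled_pr = float((grp["pr"] * grp["duration"]).sum() / total_dur)
        samples = None
        if state_samples is not None:
            parts = [state_samples[int(e)][int(s)]
                     for e, s in zip(grp["event"], grp["state"])
                     if int(s) in state_samples[int(e)]]
            if parts:
                samples = np.concatenate(parts)
        if samples is not None and samples.size >= 10:
            peak_pos, peak_sd = fit_gaussian_peak(samples)
        else:
            peak_pos, peak_sd = float(pos.mean()), float(pos.std())
        out.append({
            "position_mean": float(pos.mean()),
            "position_sd": float(pos.std(ddof=1)) if pos.size > 1 else np.nan,
            "n_events": int(grp["event"].nunique()),
            "pooled_pr": pooled_pr,
            "peak_position": peak_pos,
            "peak_sd": peak_sd,
            "fwhm": FWHM_FACTOR * peak_sd,
        })
    table = pd.DataFrame(out).sort_values("position_mean",
                                          ignore_index=True)
    return PopulationStateTable(
        table=table,
        rloop_size_stats=box_stats([ev.rloop_size for ev in events]),
        main_size_stats=box_stats([ev.main_size for ev in events]),
        n_events=len(events),
    )
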