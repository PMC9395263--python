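"""Generator behaviour: CTMC dwells, emissions, rendering, time courses,
clamp-trace grammar."""

import numpy as np
import pytest
from scipy import stats

from rloopmt.kinetics import model_fractions
from rloopmt.synthetic import (ClampSimParams, SimParams,
                               clamp_challenge_schedule, emit_turns_trace,
                               formation_schedule, render_extension,
                               simulate_clamp_events, simulate_clamp_trace,
                               simulate_state_path, simulate_timecourse)
from rloopmt.preprocess import extension_to_turns, fit_hat_linear_region


def test_absorbing_chain_single_dwell():
    p = SimParams(np.array([0.0, 1.8]), np.zeros((2, 2)), emission_sd=0.1)
    path = simulate_state_path(p, 10.0, initial_state=1)
    assert len(path.states) == 1
    assert path.states[0] == 1
    assert path.duration == pytest.approx(10.0)


def test_invalid_duration_and_state(two_state_params):
    with pytest.raises(ValueError):
        simulate_state_path(two_state_params, 0.0, 0)
    with pytest.raises(ValueError):
        simulate_state_path(two_state_params, 1.0, 5)


def test_dwell_times_exponential(two_state_params, rng):
    """Dwells of a symmetric 1/s chain: mean 1 s and exponential shape."""
    path = simulate_state_path(two_state_params, 10_000.0, 0, rng=rng)
    dwells = path.dwell_times[:-1]  # last dwell is truncated
    assert dwells.size >= 5000
    se = dwells.std(ddof=1) / np.sqrt(dwells.size)
    assert abs(dwells.mean() - 1.0) < 3 * se
    ks = stats.kstest(dwells, "expon", args=(0, 1.0))
    assert ks.pvalue > 0.01


def test_emission_noiseless_limit(two_state_params, rng):
    p = two_state_params
    path = simulate_state_path(p, 30.0, 0, rng=rng)
    p_quiet = SimParams(p.state_positions, p.rate_matrix, emission_sd=1e-15,
                        sample_rate=60.0, seed=p.seed)
    tr = emit_turns_trace(path, p_quiet, rng=rng)
    np.testing.assert_allclose(
        tr.signal, p.state_positions[tr.truth_state], atol=1e-12)


def test_emission_sd_recovered(rng):
    p = SimParams(np.array([1.8]), np.zeros((1, 1)), emission_sd=0.1,
                  sample_rate=100.0)
    path = simulate_state_path(p, 100.0, 0, rng=rng)
    tr = emit_turns_trace(path, p, rng=rng)
    assert len(tr) == 10_000
    assert abs(tr.signal.std() - 0.1) / 0.1 < 0.05


def test_trace_determinism(two_state_params):
    p = two_state_params
    out = []
    for _ in range(2):
        rng = np.random.default_rng(p.seed)
        path = simulate_state_path(p, 20.0, 0, rng=rng)
        out.append(emit_turns_trace(path, p, rng=rng))
    np.testing.assert_array_equal(out[0].signal, out[1].signal)
    np.testing.assert_array_equal(out[0].truth_state, out[1].truth_state)


def test_render_extension_roundtrip(two_state_params, rng):
    """extension_to_turns inverts render_extension on the linear branch."""
    p = two_state_params
    sch = formation_schedule(phase=30.0)
    path = simulate_state_path(p, 25.0, 0, rng=rng)
    tr = emit_turns_trace(path, p, rng=rng)
    ext = render_extension(tr, p, sch)
    hat = fit_hat_linear_region(
        p.hat_intercept + p.hat_slope * np.arange(-12.0, -3.0),
        np.arange(-12.0, -3.0), (-12, -4))
    back = extension_to_turns(ext, hat, sch)
    np.testing.assert_allclose(back.signal, tr.signal, atol=1e-9)


def test_render_extension_plateau_and_constant(two_state_params):
    p = two_state_params
    sch = formation_schedule(phase=100.0)
    t = np.arange(600) / 60.0
    # no R-loop: constant extension on the linear branch
    flat = emit_like = np.zeros(600)
    from rloopmt.trace import TurnsTrace
    tr = TurnsTrace(t, flat, 60.0, "turns")
    ext = render_extension(tr, p, sch)
    np.testing.assert_allclose(ext.signal, ext.signal[0])
    # effective turns >= 0 caps at the relaxed plateau
    tr12 = TurnsTrace(t, np.full(600, 12.0), 60.0, "turns")
    ext12 = render_extension(tr12, p, sch)
    np.testing.assert_allclose(ext12.signal, p.plateau_length)


def test_timecourse_t0_and_inactive_limit():
    tcs = simulate_timecourse(0.2, 0.01, 1.0, [0.0, 5.0], 200, seed=0)
    np.testing.assert_allclose(tcs[0].fractions[0], [1.0, 0.0, 0.0])
    tcs = simulate_timecourse(5.0, 5.0, 0.5, [0.0, 1e4], 100_000, seed=1)
    assert tcs[0].fractions[-1, 0] == pytest.approx(0.5, abs=0.01)


def test_timecourse_matches_closed_form():
    """Large-n multinomial fractions converge to the model fractions."""
    times = np.geomspace(1.0, 400.0, 6)
    n = 200_000
    tc = simulate_timecourse(0.23, 0.01, 1.0, times, n, seed=2)[0]
    sc, oc, lin = model_fractions(0.23, 0.01, 1.0, times)
    expect = np.column_stack([sc, oc, lin])
    se = np.sqrt(expect * (1 - expect) / n)
    assert np.all(np.abs(tc.fractions - expect) < 4 * se + 1e-9)
    np.testing.assert_allclose(tc.fractions.sum(axis=1), 1.0, atol=1e-12)


def test_timecourse_rejects_bad_rates():
    with pytest.raises(ValueError):
        simulate_timecourse(-0.1, 0.01, 1.0, [1.0], 10)


def test_clamp_p_stable_one_has_no_unstable(rng):
    p = ClampSimParams(p_stable=1.0)
    sch = clamp_challenge_schedule()
    for _ in range(20):
        _, ann = simulate_clamp_events(p, sch, rng=rng)
        if ann.nick_time is None:
            continue
        assert ann.n_unstable == 0


def test_clamp_immediate_closure_keeps_supercoils():
    """With near-instant clamping, no relaxed intermediate appears."""
    p = ClampSimParams(k_close=1e7, p_stable=1.0, k_ts_cut=0.5, seed=6)
    sch = clamp_challenge_schedule()
    tr, ann = simulate_clamp_trace(p, sch, seed=6)
    assert ann.nick_time is not None
    post = tr.signal[tr.time > ann.nick_time]
    # the trace never returns to full length before bead loss
    assert np.all(post < -2.0)


def test_clamp_unstable_fraction_matches_geometric(rng):
    """p_stable = 0.5: half of nicked traces show >= 1 unstable clamp."""
    p = ClampSimParams(p_stable=0.5)
    sch = clamp_challenge_schedule()
    n_unstable = n = 0
    for _ in range(400):
        _, ann = simulate_clamp_events(p, sch, rng=rng)
        if ann.nick_time is None or not (ann.has_stable or ann.censored):
            continue
        n += 1
        n_unstable += ann.n_unstable >= 1
    frac = n_unstable / n
    se = np.sqrt(0.25 / n)
    assert abs(frac - 0.5) < 3 * se


def test_clamp_annotation_tiles_nick_to_bead_loss(rng):
    p = ClampSimParams()
    sch = clamp_challenge_schedule()
    checked = 0
    for _ in range(50):
        _, ann = simulate_clamp_events(p, sch, rng=rng)
        if ann.nick_time is None or ann.bead_loss_time is None:
            continue
        ann.validate()
        assert ann.intervals[0].start == pytest.approx(ann.nick_time)
        assert ann.intervals[-1].end == pytest.approx(ann.bead_loss_time)
        for a, b in zip(ann.intervals, ann.intervals[1:]):
            assert b.start == pytest.approx(a.end)
        checked += 1
    assert checked > 10


def test_clamp_trace_determinism():
    p = ClampSimParams(seed=9)
    sch = clamp_challenge_schedule()
    t1, a1 = simulate_clamp_trace(p, sch, seed=9)
    t2, a2 = simulate_clamp_trace(p, sch, seed=9)
    np.testing.assert_array_equal(t1.signal, t2.signal)
    assert a1.nick_time == a2.nick_time
    assert a1.release_steps == a2.release_steps
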