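"""Step detection, clamp-interval classification and comparison statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from rloopmt.clamp import (ClampAnnotation, ClampInterval,
                           classify_clamp_intervals, detect_steps,
                           overhang_length, release_step_histogram,
                           two_proportion_ztest)
from rloopmt.synthetic import (ClampSimParams, clamp_challenge_schedule,
                               simulate_clamp_events, simulate_clamp_trace)
from rloopmt.trace import MagnetSchedule, TurnsTrace


def _trace(signal, rate=60.0):
    n = len(signal)
    return TurnsTrace(np.arange(n) / rate, np.asarray(signal, float), rate,
                      "turns")


class TestDetectSteps:
    def test_noiseless_single_step_exact(self):
        sig = np.zeros(600)
        sig[300:] = 12.0
        steps = detect_steps(_trace(sig), min_dwell=0.1)
        assert len(steps) == 1
        assert steps.step_times[0] == pytest.approx(300 / 60.0, abs=1 / 60.0)
        assert steps.step_sizes[0] == pytest.approx(12.0)

    def test_constant_trace_no_steps(self):
        assert len(detect_steps(_trace(np.full(500, 3.0)))) == 0

    def test_three_step_release_recovered(self):
        """A staircase release (3 steps, noise sd 0.3 turns) is recovered
        with every step within 0.2 s in >= 90% of seeded traces."""
        rate = 60.0
        truth_times = np.array([5.0, 5.4, 5.8])
        hits = 0
        n = 50
        master = np.random.default_rng(7)
        for _ in range(n):
            rng = np.random.default_rng(master.integers(2 ** 31))
            t = np.arange(int(10 * rate)) / rate
            sig = np.full(t.size, -12.0)
            for tt in truth_times:
                sig[t >= tt] += 4.0
            sig = sig + rng.normal(0, 0.3, t.size)
            steps = detect_steps(TurnsTrace(t, sig, rate, "turns"),
                                 min_dwell=0.1)
            up = steps.step_times[steps.step_sizes > 0]
            if len(up) == 3 and np.all(np.abs(up - truth_times) <= 0.2):
                hits += 1
        assert hits >= 0.9 * n


class TestClassifyClampIntervals:
    def test_p_stable_one_single_stable_interval(self):
        p = ClampSimParams(p_stable=1.0, seed=21)
        sch = clamp_challenge_schedule()
        for seed in range(6):
            tr, truth = simulate_clamp_trace(p, sch, seed=30 + seed)
            if truth.nick_time is None or truth.bead_loss_time is None:
                continue
            # only evaluable when the stable clamp was torque-challenged,
            # held trapped supercoils at the cut, and closed while the
            # magnets were stationary (a mid-ramp closure traps only a
            # partial linking difference, which sits at the detection
            # threshold)
            def mid_ramp(t):
                return any(sch.breakpoints[i] <= t <= sch.ramp_end(i)
                           for i in range(1, len(sch.breakpoints)))
            visible = any(
                iv.kind == "clamped_stable"
                and any(iv.start < sch.ramp_end(i) < iv.end - 1.0
                        for i in range(1, len(sch.breakpoints)))
                and abs(sch.applied_at(iv.end) - sch.applied_at(iv.start)) > 2
                and not mid_ramp(iv.start)
                for iv in truth.intervals)
            if not visible:
                continue
            steps = detect_steps(tr, min_dwell=0.1)
            ann = classify_clamp_intervals(tr, sch, steps)
            assert ann.has_stable
            assert ann.n_unstable == 0

    def test_pure_nicked_rotor_no_clamps(self, rng):
        """k_close = 0: rotation never shortens the nicked DNA."""
        p = ClampSimParams(k_close=0.0, seed=5)
        sch = clamp_challenge_schedule(n_challenges=6)
        tr, truth = simulate_clamp_trace(p, sch, seed=5)
        assert truth.nick_time is not None
        steps = detect_steps(tr, min_dwell=0.1)
        ann = classify_clamp_intervals(tr, sch, steps,
                                       ended_by_bead_loss=False)
        assert ann.nick_time == pytest.approx(truth.nick_time, abs=0.3)
        assert sum(iv.kind.startswith("clamped") for iv in ann.intervals) == 0

    def test_confusion_rate_below_5_percent(self):
        from rloopmt.benchmarks import clamp_confusion
        out = clamp_confusion(n_traces=200, seed=11)
        assert out["n_comparisons"] > 50
        assert out["confusion_rate"] < 0.05

    def test_time_shift_invariance(self):
        p = ClampSimParams(seed=13)
        sch = clamp_challenge_schedule()
        tr, truth = simulate_clamp_trace(p, sch, seed=13)
        if truth.nick_time is None:
            pytest.skip("trace censored before nick")
        steps = detect_steps(tr, min_dwell=0.1)
        ann = classify_clamp_intervals(tr, sch, steps)
        dt = 100.0
        tr2 = TurnsTrace(tr.time + dt, tr.signal, tr.sample_rate, "turns")
        sch2 = MagnetSchedule(sch.breakpoints + dt, sch.applied_turns,
                              sch.rotation_rate, sch.force,
                              None if sch.end_time is None
                              else sch.end_time + dt)
        steps2 = detect_steps(tr2, min_dwell=0.1)
        ann2 = classify_clamp_intervals(tr2, sch2, steps2)
        assert ann2.nick_time == pytest.approx(ann.nick_time + dt, abs=1e-6)
        assert len(ann2.intervals) == len(ann.intervals)
        for a, b in zip(ann.intervals, ann2.intervals):
            assert b.kind == a.kind
            assert b.start == pytest.approx(a.start + dt, abs=1e-6)

    def test_time_to_stable_matches_composition_oracle(self):
        """Against a schedule with no early challenges, the nick-to-stable
        waiting time matches the geometric composition of closure/opening
        waits (two-sample KS at alpha = 0.01, 500 traces)."""
        p = ClampSimParams(p_stable=0.3, seed=0)
        sch = clamp_challenge_schedule(first_challenge=4000.0, period=10.0,
                                       n_challenges=2)
        rng = np.random.default_rng(17)
        waits = []
        for _ in range(500):
            _, ann = simulate_clamp_events(p, sch, rng=rng)
            if ann.nick_time is None or not ann.has_stable:
                continue
            stable = ann.intervals[-1]
            waits.append(stable.start - ann.nick_time)
        # independent Monte Carlo oracle from the composed distributions
        orng = np.random.default_rng(18)
        n_unstable = orng.geometric(p.p_stable, size=20_000) - 1
        oracle = np.array([
            orng.exponential(1 / p.k_close, nu + 1).sum()
            + orng.exponential(1 / p.k_open, nu).sum()
            for nu in n_unstable])
        ks = stats.ks_2samp(np.array(waits), oracle)
        assert len(waits) > 400
        assert ks.pvalue > 0.01


class TestReleaseStepHistogram:
    def test_single_step_mass(self):
        anns = [ClampAnnotation(nick_time=1.0, release_steps=[1, 1, 1])]
        counts, fracs = release_step_histogram(anns)
        np.testing.assert_array_equal(counts, [3, 0, 0, 0, 0])
        assert fracs.sum() == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            release_step_histogram([ClampAnnotation(nick_time=None)])

    def test_uniform_distribution_recovered(self, rng):
        """500 releases from a uniform 1-5 law: every bin near 0.2."""
        p = ClampSimParams(p_stable=0.0)
        sch = clamp_challenge_schedule()
        anns = []
        pooled = 0
        while pooled < 500:
            _, ann = simulate_clamp_events(p, sch, rng=rng)
            anns.append(ann)
            pooled += len(ann.release_steps)
        _, fracs = release_step_histogram(anns)
        se = np.sqrt(0.2 * 0.8 / pooled)
        assert np.all(np.abs(fracs - 0.2) < 3 * se + 1e-9)


class TestOverhangLength:
    @pytest.mark.parametrize("nts,ts,expect", [
        (18, 22, 4), (18, 23, 5), (18, 24, 6), (20, 20, 0)])
    def test_printed_loci(self, nts, ts, expect):
        assert overhang_length(nts, ts) == expect

    def test_three_prime_flagged_and_non_integer_rejected(self):
        with pytest.warns(UserWarning):
            assert overhang_length(22, 18) == -4
        with pytest.raises(ValueError):
            overhang_length(18.5, 22)


class TestTwoProportionZTest:
    def test_equal_proportions(self):
        z, p = two_proportion_ztest(5, 10, 5, 10)
        assert z == pytest.approx(0.0)
        assert p == pytest.approx(0.5)

    def test_against_chi_square_oracle(self):
        """z^2 equals the (uncorrected) chi-square of the 2x2 table."""
        z, p = two_proportion_ztest(8, 10, 2, 10)
        assert z == pytest.approx(2.683, abs=1e-3)
        table = np.array([[8, 2], [2, 8]])
        chi2 = stats.chi2_contingency(table, correction=False)[0]
        assert z ** 2 == pytest.approx(chi2, rel=1e-9)

    def test_errors(self):
        with pytest.raises(ValueError):
            two_proportion_ztest(1, 0, 1, 2)
        with pytest.raises(ValueError):
            two_proportion_ztest(0, 10, 0, 10)

    @given(x1=st.integers(0, 20), x2=st.integers(0, 20))
    @settings(max_examples=60, deadline=None)
    def test_antisymmetry(self, x1, x2):
        if x1 + x2 in (0, 40):
            return
        z1, _ = two_proportion_ztest(x1, 20, x2, 20)
        z2, _ = two_proportion_ztest(x2, 20, x1, 20)
        assert z1 == pytest.approx(-z2, abs=1e-12)
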