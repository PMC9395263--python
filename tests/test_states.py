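"""HMM fitting, Viterbi decoding, model selection and state statistics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rloopmt.preprocess import decimate
from rloopmt.states import (CalibrationConstant, StateModel, box_stats,
                            event_statistics, fit_gaussian_hmm,
                            fit_gaussian_peak, gaussian_state_positions,
                            rupture_probability, select_state_number,
                            turns_to_bp, viterbi_path, aggregate_population,
                            FWHM_FACTOR)
from rloopmt.synthetic import (SimParams, birth_death_rate_matrix,
                               emit_turns_trace, simulate_state_path)
from rloopmt.trace import StatePath, TurnsTrace


def _trace(signal, rate=10.0):
    n = len(signal)
    return TurnsTrace(np.arange(n) / rate, np.asarray(signal, float), rate,
                      "turns")


class TestFitGaussianHMM:
    def test_noiseless_square_wave_positions_exact(self):
        sig = np.tile(np.repeat([0.0, 1.8], 25), 8)
        model = fit_gaussian_hmm(_trace(sig), 2, n_restarts=3, seed=0)
        np.testing.assert_allclose(model.positions, [0.0, 1.8], atol=1e-6)

    def test_single_state_is_trace_mean(self, rng):
        sig = rng.normal(1.1, 0.1, 300)
        model = fit_gaussian_hmm(_trace(sig), 1)
        assert model.positions[0] == pytest.approx(sig.mean(), abs=1e-12)

    def test_five_state_positions_recovered(self, five_state_params):
        # seed chosen so every state is visited for several seconds
        rng = np.random.default_rng(4)
        path = simulate_state_path(five_state_params, 80.0, 0, rng=rng)
        assert min(path.total_time_in(s) for s in range(5)) > 5.0
        tr = emit_turns_trace(path, five_state_params, rng=rng)
        model = fit_gaussian_hmm(tr, 5, n_restarts=5, seed=1)
        np.testing.assert_allclose(model.positions,
                                   five_state_params.state_positions,
                                   atol=0.05)

    def test_degenerate_trace_rejected(self):
        with pytest.raises(ValueError):
            fit_gaussian_hmm(_trace(np.ones(100)), 2)

    def test_deterministic_under_seed(self, five_state_params, rng):
        path = simulate_state_path(five_state_params, 40.0, 0, rng=rng)
        tr = emit_turns_trace(path, five_state_params, rng=rng)
        m1 = fit_gaussian_hmm(tr, 4, seed=7)
        m2 = fit_gaussian_hmm(tr, 4, seed=7)
        np.testing.assert_array_equal(m1.positions, m2.positions)


class TestViterbi:
    def test_noiseless_labels_recovered(self, two_state_params, rng):
        p = two_state_params
        quiet = SimParams(p.state_positions, p.rate_matrix,
                          emission_sd=1e-6, sample_rate=60.0, seed=p.seed)
        path = simulate_state_path(quiet, 30.0, 0, rng=rng)
        tr = emit_turns_trace(path, quiet, rng=rng)
        model = fit_gaussian_hmm(tr, 2, seed=0)
        decoded = viterbi_path(model, tr)
        np.testing.assert_array_equal(decoded.labels, tr.truth_state)

    def test_single_state_constant_path(self, rng):
        sig = rng.normal(0.5, 0.1, 120)
        model = fit_gaussian_hmm(_trace(sig), 1)
        path = viterbi_path(model, _trace(sig))
        assert len(path.states) == 1

    @pytest.mark.parametrize("k,n", [(2, 10), (3, 8)])
    def test_viterbi_beats_exhaustive_enumeration(self, k, n, rng):
        """The decoded path maximises the joint probability over all k^n
        state sequences (brute-force oracle on short traces)."""
        positions = np.linspace(0.0, 1.8, k)
        model = StateModel(
            k, positions, np.full(k, 0.3),
            np.full((k, k), 0.2 / (k - 1)) + np.eye(k) * (0.8 - 0.2 / (k - 1)),
            0.0, startprob=np.full(k, 1 / k))
        sig = rng.normal(positions[rng.integers(k, size=n)], 0.3)
        tr = _trace(sig)
        decoded = viterbi_path(model, tr)

        def logp(seq):
            lp = np.log(model.startprob[seq[0]])
            for a, b in zip(seq, seq[1:]):
                lp += np.log(model.transition_matrix[a, b])
            for s, x in zip(seq, sig):
                sd = model.emission_sd[s]
                lp += -0.5 * ((x - positions[s]) / sd) ** 2 - np.log(sd)
            return lp

        best = max(itertools.product(range(k), repeat=n), key=logp)
        assert logp(tuple(decoded.labels)) >= logp(best) - 1e-9


class TestGaussianPositions:
    def test_peak_matches_sample_moments(self, rng):
        samples = rng.normal(1.8, 0.1, 5000)
        mu, sd = fit_gaussian_peak(samples)
        assert mu == pytest.approx(samples.mean(), abs=0.01)
        assert sd == pytest.approx(samples.std(), rel=0.1)

    def test_symmetric_histogram_peak_is_mean(self):
        from scipy.stats import norm
        # exactly symmetric Gaussian-shaped sample set around 1.8
        offsets = 0.1 * norm.ppf((np.arange(2000) + 0.5) / 2000)
        mu, _ = fit_gaussian_peak(1.8 + offsets)
        assert mu == pytest.approx(1.8, abs=1e-6)

    def test_fwhm_identity_and_underoccupied_flag(self, rng):
        sig = np.concatenate([rng.normal(0, 0.05, 500),
                              rng.normal(1.8, 0.05, 10)])
        tr = _trace(sig)
        model = StateModel(2, np.array([0.0, 1.8]), np.array([0.05, 0.05]),
                           np.array([[0.99, 0.01], [0.01, 0.99]]), 0.0)
        path = viterbi_path(model, tr)
        peaks = gaussian_state_positions(model, path, tr)
        for p in peaks:
            assert p.fwhm == pytest.approx(FWHM_FACTOR * p.sd, abs=1e-9)
        assert peaks[0].included
        assert not peaks[1].included  # < 20 samples


class TestSelectStateNumber:
    def test_two_levels_select_two(self, rng):
        sig = np.repeat(rng.integers(0, 2, 80), 10) * 1.8 \
            + rng.normal(0, 0.05, 800)
        sel = select_state_number(_trace(sig), k_max=4, seed=0)
        assert sel.model.n_states == 2
        np.testing.assert_allclose(sel.model.positions, [0, 1.8], atol=0.02)

    def test_close_states_merged_by_separation_rule(self, rng):
        """Levels 0.05 turns apart cannot pass the >0.1-turn rule."""
        levels = np.array([0.0, 1.75, 1.80])
        seq = rng.integers(0, 3, 150)
        sig = np.repeat(levels[seq], 8) + rng.normal(0, 0.04, 1200)
        sel = select_state_number(_trace(sig), k_max=3, seed=1)
        assert sel.model.n_states == 2

    def test_five_state_recovery_rate(self, five_state_params):
        """>= 90% of seeded events select k = 5 with all positions within
        0.05 turns of the generator truth."""
        truth = five_state_params.state_positions
        master = np.random.default_rng(42)
        hits = 0
        n = 50
        for _ in range(n):
            rng = np.random.default_rng(master.integers(2 ** 31))
            path = simulate_state_path(five_state_params, 80.0, 0, rng=rng)
            tr = emit_turns_trace(path, five_state_params, rng=rng)
            sel = select_state_number(tr, k_max=5, n_restarts=3,
                                      seed=int(master.integers(2 ** 31)))
            if sel.model.n_states == 5 and np.all(
                    np.abs(sel.model.positions - truth) < 0.05):
                hits += 1
        assert hits >= 0.9 * n


class TestEventStatistics:
    def _model(self):
        return StateModel(2, np.array([0.0, 1.8]), np.array([0.1, 0.1]),
                          np.array([[0.9, 0.1], [0.1, 0.9]]), 0.0)

    def test_occupancy_arithmetic(self):
        path = StatePath(np.array([1, 0]), np.array([0.0, 30.0]),
                         np.array([30.0, 100.0]))
        ev = event_statistics(path, self._model(), (0.0, 100.0),
                              min_dwell=0.5)
        np.testing.assert_allclose(ev.occupancy, [0.7, 0.3])
        assert ev.occupancy.sum() == pytest.approx(1.0)
        assert ev.rloop_size == pytest.approx(1.8)

    def test_transient_excursion_excluded_from_size(self):
        path = StatePath(np.array([0, 1, 0]), np.array([0.0, 50.0, 50.2]),
                         np.array([50.0, 50.2, 100.0]))
        ev = event_statistics(path, self._model(), (0.0, 100.0),
                              min_dwell=0.5)
        assert ev.rloop_size == pytest.approx(0.0)

    def test_empty_window_rejected(self):
        path = StatePath(np.array([0]), np.array([0.0]), np.array([1.0]))
        with pytest.raises(ValueError):
            event_statistics(path, self._model(), (5.0, 5.0))


class TestRuptureProbability:
    def test_counting(self):
        path = StatePath(np.array([1, 0, 1, 0, 1]),
                         np.arange(5) * 20.0, np.arange(1, 6) * 20.0)
        assert rupture_probability(path, 0, 100.0) == pytest.approx(0.02)
        path2 = StatePath(np.array([1, 2, 1]), np.arange(3) * 10.0,
                          np.arange(1, 4) * 10.0)
        assert rupture_probability(path2, 0, 30.0) == 0.0

    def test_rate_recovered_from_ctmc(self, two_state_params, rng):
        """Entry rate into the basal state matches the stationary flux
        pi_rloop * k within 3 Poisson standard errors."""
        total_t, count = 0.0, 0
        for _ in range(200):
            path = simulate_state_path(two_state_params, 50.0, 1, rng=rng)
            count += rupture_probability(path, 0, 50.0) * 50.0
            total_t += 50.0
        rate = count / total_t
        expected = 0.5 * 1.0  # pi_1 * k_10
        se = np.sqrt(count) / total_t
        assert abs(rate - expected) < 3 * se


class TestCalibration:
    def test_calibration_values(self):
        cal = CalibrationConstant()
        assert turns_to_bp(1.8, cal) == pytest.approx(20.0)
        assert turns_to_bp(0.0, cal) == 0.0
        # breathing state: ~2 bp beyond the 20-bp R-loop
        assert turns_to_bp(2.0, cal) == pytest.approx(22.22, abs=0.01)
        assert round(turns_to_bp(2.0, cal)) - 20 == 2

    @given(a=st.floats(-5, 5), b=st.floats(-5, 5))
    @settings(max_examples=50, deadline=None)
    def test_linearity(self, a, b):
        cal = CalibrationConstant()
        assert turns_to_bp(a + b, cal) == pytest.approx(
            turns_to_bp(a, cal) + turns_to_bp(b, cal), abs=1e-9)


class TestAggregatePopulation:
    def test_box_stats_quantile_oracle(self):
        s = box_stats(np.arange(1, 101))
        assert s["median"] == pytest.approx(50.5)
        assert s["whisker_lo"] == pytest.approx(10.9)
        assert s["whisker_hi"] == pytest.approx(90.1)
        assert s["iqr"] == pytest.approx(49.5)  # linear-interp quantiles

    def test_identical_events_zero_sd(self):
        from rloopmt.states import EventRecord
        ev = EventRecord((0.0, 50.0), np.array([0.3, 0.7]),
                         np.array([0.0, 1.0]), np.array([0.0, 1.8]),
                         1.8, 1.8, 1, 2, 50.0)
        pop = aggregate_population([ev, ev])
        assert np.allclose(pop.table["position_sd"], 0.0)
        # pooled P_r is the duration-weighted mean of per-event P_r
        np.testing.assert_allclose(sorted(pop.table["pooled_pr"]),
                                   [0.3, 0.7], atol=1e-9)
        assert pop.table["pooled_pr"].sum() == pytest.approx(1.0)
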