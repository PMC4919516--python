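"""Response quantification: PSTH, delta-R, significance calls, normalization."""

import numpy as np
import pytest
from scipy import stats

from aobt import (
    AnalysisWindows,
    GeneratorConfig,
    ResponseModel,
    call_response,
    compute_delta_r,
    compute_dff,
    compute_psth,
    normalize_tuning,
    simulate_session,
)
from aobt.response import call_control_response
from aobt.session import SpikeTrain, StimulusEvent

from conftest import make_session

W = AnalysisWindows()
EVENT = StimulusEvent("a", onset=50.0, offset=54.0, repeat_index=1)


def brute_delta_r(times, event, w=W):
    """Independent oracle: explicit per-spike window membership counting."""
    resp = sum(
        1 for t in times
        if event.onset + w.response_start <= t < event.onset + w.response_end
    )
    base = sum(
        1 for t in times
        if event.onset - w.baseline_duration <= t < event.onset
    )
    return resp / w.response_duration - base / w.baseline_duration


def brute_psth(times, events, w=W):
    """Independent oracle: per-bin loop counting."""
    n_bins = w.n_psth_bins
    acc = np.zeros(n_bins)
    for e in events:
        for b in range(n_bins):
            lo = e.onset - w.psth_pre + b * w.psth_bin
            hi = lo + w.psth_bin
            acc[b] += sum(1 for t in times if lo <= t < hi) / w.psth_bin
    return acc / len(events)


class TestWindows:
    def test_default_geometry(self):
        assert W.response_duration == 4.0
        assert W.n_psth_bins == 20

    def test_degenerate_window_rejected(self):
        with pytest.raises(ValueError):
            AnalysisWindows(response_start=5.0, response_end=5.0)


class TestPsth:
    def test_empty_train_is_zero(self):
        rates, sem = compute_psth(SpikeTrain("c", np.empty(0)), [EVENT])
        assert rates.shape == (20,)
        assert not rates.any()

    def test_single_event_manual_count(self):
        # spikes at onset+0.5 and onset+1.5 fall in the 6th and 7th bins
        train = SpikeTrain("c", np.array([EVENT.onset + 0.5, EVENT.onset + 1.5]))
        rates, _ = compute_psth(train, [EVENT])
        expected = np.zeros(20)
        expected[5] = expected[6] = 1.0
        np.testing.assert_array_equal(rates, expected)

    def test_flat_poisson_is_flat(self):
        rng = np.random.default_rng(4)
        lam, n_ev = 5.0, 50
        events = [
            StimulusEvent("a", 10.0 + 25.0 * k, 14.0 + 25.0 * k, k + 1)
            for k in range(n_ev)
        ]
        T = events[-1].offset + 20.0
        times = np.sort(rng.uniform(0, T, rng.poisson(lam * T)))
        times = times[np.concatenate(([True], np.diff(times) > 0))]
        rates, _ = compute_psth(SpikeTrain("c", times), events)
        se = np.sqrt(lam / (1.0 * n_ev))  # Poisson s.e. of a per-bin mean rate
        assert np.all(np.abs(rates - lam) < 4 * se)

    def test_psth_mass_equals_mean_window_count(self):
        rng = np.random.default_rng(8)
        events = [
            StimulusEvent("a", 20.0 + 30.0 * k, 24.0 + 30.0 * k, k + 1)
            for k in range(5)
        ]
        times = np.sort(rng.uniform(0, 200, 300))
        times = times[np.concatenate(([True], np.diff(times) > 0))]
        train = SpikeTrain("c", times)
        rates, _ = compute_psth(train, events)
        mean_count = np.mean([
            np.sum((times >= e.onset - 5.0) & (times < e.onset + 15.0))
            for e in events
        ])
        assert np.isclose(rates.sum() * 1.0, mean_count)

    def test_matches_brute_force_random_instances(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            n_ev = int(rng.integers(1, 4))
            events = [
                StimulusEvent("a", 10.0 + 25.0 * k, 14.0 + 25.0 * k, k + 1)
                for k in range(n_ev)
            ]
            times = np.sort(rng.uniform(0, 120, int(rng.integers(0, 80))))
            times = times[np.concatenate(([True], np.diff(times) > 0))] if times.size else times
            rates, _ = compute_psth(SpikeTrain("c", times), events)
            np.testing.assert_allclose(rates, brute_psth(times, events), atol=1e-10)


class TestDeltaR:
    def test_arithmetic_example(self):
        # 10 baseline spikes over 5 s, 12 response spikes over 4 s -> 3-2=1
        base = EVENT.onset - 5.0 + np.linspace(0.1, 4.9, 10)
        resp = EVENT.onset + 1.0 + np.linspace(0.1, 3.9, 12)
        train = SpikeTrain("c", np.sort(np.concatenate([base, resp])))
        assert compute_delta_r(train, EVENT) == pytest.approx(1.0)

    def test_no_spikes_is_zero(self):
        assert compute_delta_r(SpikeTrain("c", np.empty(0)), EVENT) == 0.0

    def test_planted_effect_recovered(self):
        cfg = GeneratorConfig(n_cells=1, stimulus_ids=["a"], baseline_rate=1.0,
                              effects={0: {"a": 10.0}}, n_trials=30,
                              jitter_sd=0.0, seed=21)
        s = simulate_session(cfg)
        drs = [compute_delta_r(s.trains[0], e) for e in s.events_for("a")]
        # var(dR) = lam_resp/4 + lam_base/5 = 11/4 + 1/5
        sem = np.sqrt((11 / 4 + 1 / 5) / len(drs))
        assert abs(np.mean(drs) - 10.0) < 4 * sem

    def test_matches_brute_force_random_instances(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            times = np.sort(rng.uniform(0, 120, int(rng.integers(0, 60))))
            times = times[np.concatenate(([True], np.diff(times) > 0))] if times.size else times
            onset = float(rng.uniform(10, 90))
            ev = StimulusEvent("a", onset, onset + 4.0, 1)
            got = compute_delta_r(SpikeTrain("c", times), ev)
            assert got == pytest.approx(brute_delta_r(times, ev), abs=1e-10)


class TestCallResponse:
    def test_identical_draws_not_significant(self):
        x = [1.0, 2.0, 3.0, 2.0, 1.5]
        call = call_response(x, x)
        assert call.significant is False

    def test_rate_criterion_blocks_small_increase(self):
        # clearly separable distributions but mean increase below 1 Hz
        x = [0.80, 0.81, 0.79, 0.80, 0.80]
        y = [0.0, 0.01, -0.01, 0.0, 0.0]
        call = call_response(x, y)
        assert call.t_test_pass is True
        assert call.rate_pass is False
        assert call.significant is False

    def test_under_three_trials_unanalyzable(self):
        call = call_response([5.0, 6.0], [0.0, 0.1, 0.0])
        assert call.significant is None
        assert call.reason == "insufficient trials"

    def test_welch_flag_changes_test(self):
        rng = np.random.default_rng(0)
        x = rng.normal(2, 3, 8)
        y = rng.normal(0, 0.3, 8)
        p_student = call_response(x, y, equal_var=True).p_value
        p_welch = call_response(x, y, equal_var=False).p_value
        assert p_student != p_welch
        assert p_welch == pytest.approx(
            stats.ttest_ind(x, y, equal_var=False).pvalue
        )

    def test_window_rate_criterion(self):
        x = [3.0, 3.2, 2.8, 3.1, 3.0]
        y = [0.0, 0.1, -0.1, 0.0, 0.05]
        low_rates = [0.9, 0.8, 0.95, 0.85, 0.9]
        call = call_response(x, y, criterion="window_rate", window_rates=low_rates)
        assert call.rate_pass is False

    def test_planted_response_power(self):
        # Delta=10 Hz over lam0=1 with 5 trials: detection is near-certain
        cfg = GeneratorConfig(n_cells=50, stimulus_ids=["a"], baseline_rate=1.0,
                              effects={c: {"a": 10.0} for c in range(50)},
                              n_trials=5, seed=17)
        res = ResponseModel(simulate_session(cfg)).fit()
        sig = res.significance_table(included_only=False)["a"]
        assert sig.mean() >= 0.98

    def test_control_self_response_detected(self):
        assert call_control_response([5.0, 5.5, 6.0, 5.2]).significant is True
        assert call_control_response([0.0, 0.1, -0.1, 0.05]).significant is False


class TestInclusion:
    def _results(self, effects, seed=7, n_cells=3):
        cfg = GeneratorConfig(n_cells=n_cells, stimulus_ids=["a", "b"],
                              effects=effects, baseline_rate=1.0, seed=seed)
        return ResponseModel(simulate_session(cfg)).fit()

    def test_non_responder_excluded(self):
        res = self._results({0: {"a": 10.0}})
        inc = res.inclusion.set_index("cell_id")
        assert not inc.at["cell001", "included"]
        assert inc.at["cell001", "reason"] == "no response"

    def test_responder_included(self):
        res = self._results({0: {"a": 10.0}})
        assert "cell000" in res.included_cells

    def test_control_responder_excluded(self):
        # inject a strong control response by hand-editing the trial dR:
        # simplate a cell whose spikes bulk up in every control window
        cfg = GeneratorConfig(n_cells=1, stimulus_ids=["a"],
                              effects={0: {"a": 10.0}}, baseline_rate=1.0, seed=3)
        s = simulate_session(cfg)
        extra = np.concatenate([
            np.linspace(e.onset + 1.01, e.onset + 4.99, 40)
            for e in s.events_for("ringers")
        ])
        merged = np.unique(np.concatenate([s.trains[0].spike_times, extra]))
        s.trains[0] = type(s.trains[0])("cell000", merged)
        res = ResponseModel(s).fit()
        inc = res.inclusion.set_index("cell_id")
        assert not inc.at["cell000", "included"]
        assert inc.at["cell000", "reason"] == "control responsive"


class TestNormalize:
    def test_arithmetic_example(self):
        np.testing.assert_allclose(
            normalize_tuning([2.0, 4.0, -1.0]), [0.5, 1.0, -0.25]
        )

    def test_single_entry(self):
        np.testing.assert_allclose(normalize_tuning([3.0]), [1.0])

    @pytest.mark.parametrize("seed", range(10))
    def test_max_abs_is_one(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal(0, 5, rng.integers(1, 8))
        if not np.any(v):
            v[0] = 1.0
        assert np.max(np.abs(normalize_tuning(v))) == pytest.approx(1.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            normalize_tuning([0.0, 0.0])


class TestDff:
    def test_simple_ratio(self):
        assert compute_dff([100, 100, 100, 120, 120, 120], 3) == pytest.approx(1.2)

    def test_identity(self):
        assert compute_dff([50, 50, 50, 50, 50, 50], 3) == pytest.approx(1.0)

    def test_uneven_stacks(self):
        assert compute_dff([90, 100, 110, 200, 210, 190], 3) == pytest.approx(2.0)

    def test_errors(self):
        with pytest.raises(ValueError, match="stacks"):
            compute_dff([1, 2, 3, 4], 2)
        with pytest.raises(ValueError, match="zero"):
            compute_dff([0, 0, 0, 1, 1, 1], 3)


class TestModelPlumbing:
    def test_tuning_matrix_normalized_bounds(self, planted_session):
        res = ResponseModel(planted_session).fit()
        mat = res.tuning_matrix(normalized=True, included_only=True)
        assert (mat.abs().max(axis=1) <= 1.0 + 1e-12).all()
        assert np.allclose(mat.abs().max(axis=1), 1.0)

    def test_out_of_span_events_dropped(self):
        # an event 2 s after start has no complete baseline window
        s = make_session({"c0": list(np.arange(0.5, 200.0, 0.9))})
        early = type(s.trials[0])("s1", 2.0, 6.0, 9)
        s.trials.append(early)
        res = ResponseModel(s).fit()
        assert all(e.onset != 2.0 for e in res.events)

    def test_summary_mentions_counts(self, planted_session):
        text = ResponseModel(planted_session).fit().summary()
        assert "cells included" in text
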