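"""Waiting-time extraction and Kaplan-Meier estimation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from burstkin import (
    FluorescenceTrace,
    InitiationEventTrain,
    WaitingTimeSet,
    activation_stats,
    extract_waiting_times,
    integral_amplitude,
    km_survival,
    pool_genotype,
    window_trace,
)


def _trace(values):
    values = np.asarray(values, dtype=float)
    return FluorescenceTrace(0, 3.86 * np.arange(values.size), values)


class TestWindow:
    def test_constant_trace_full_extent(self):
        tr = _trace([4.0] * 6)
        assert window_trace(tr) == (0.0, 5 * 3.86)

    def test_fifth_of_max_threshold(self):
        tr = _trace([0, 0, 5, 9, 10, 4, 1, 0])
        # max 10 -> threshold 2: frames 2..5 qualify (1-based frames 3..6)
        t0, t1 = window_trace(tr)
        assert t0 == pytest.approx(2 * 3.86)
        assert t1 == pytest.approx(5 * 3.86)

    def test_single_positive_frame(self):
        tr = _trace([0, 7, 0])
        assert window_trace(tr) == (3.86, 3.86)

    def test_all_zero_returns_none(self):
        assert window_trace(_trace([0, 0, 0])) is None


class TestExtract:
    def test_observed_and_censored(self):
        train = InitiationEventTrain(0, np.array([10.0, 19.0, 31.0]), (0.0, 40.0))
        wt = extract_waiting_times(train, (0.0, 40.0))
        assert wt.observed().tolist() == [9.0, 12.0]
        assert wt.values[wt.censored].tolist() == [9.0]

    def test_single_event_only_censored_tail(self):
        train = InitiationEventTrain(0, np.array([10.0]), (0.0, 40.0))
        wt = extract_waiting_times(train, (0.0, 40.0))
        assert wt.n_observed == 0
        assert wt.values[wt.censored].tolist() == [30.0]

    def test_no_censoring_flag(self):
        train = InitiationEventTrain(0, np.array([10.0, 19.0]), (0.0, 40.0))
        wt = extract_waiting_times(train, (0.0, 40.0), censor_final=False)
        assert wt.values.tolist() == [9.0]

    def test_train_inside_window_counts(self):
        times = np.arange(5.0, 100.0, 7.0)
        train = InitiationEventTrain(0, times, (0.0, 120.0))
        wt = extract_waiting_times(train, (0.0, 120.0))
        assert wt.n_observed == times.size - 1
        assert wt.censored.sum() == 1

    def test_pooled_mean_matches_renewal_rate(self, sna_model, sna_params):
        # mean inter-initiation interval ~ 1 / (p_ON * k_ini)
        from burstkin import derived_kinetics, simulate_event_train

        dk = derived_kinetics(sna_model)
        train = simulate_event_train(sna_model, 200_000.0, seed=21)
        deltas = np.diff(train.event_times)
        expect = 1.0 / (dk.p_ON * sna_model.k_ini)
        assert np.mean(deltas) == pytest.approx(expect, rel=0.03)


class TestPooling:
    def _wt(self, vals, genotype="g"):
        vals = np.asarray(vals, dtype=float)
        return WaitingTimeSet(vals, np.zeros(vals.size, bool), genotype=genotype)

    def test_counts_add(self):
        pooled = pool_genotype([self._wt([1, 2]), self._wt([3.0])])
        assert pooled.values.size == 3

    def test_empty_input(self):
        assert pool_genotype([]).values.size == 0

    def test_mixed_genotypes_rejected(self):
        with pytest.raises(ValueError):
            pool_genotype([self._wt([1.0], "a"), self._wt([2.0], "b")])

    @settings(deadline=None, max_examples=20)
    @given(st.permutations([1.0, 2.5, 3.0, 7.0, 11.0]))
    def test_pooling_is_order_invariant(self, order):
        sets = [self._wt([v]) for v in order]
        pooled = pool_genotype(sets)
        assert sorted(pooled.values.tolist()) == [1.0, 2.5, 3.0, 7.0, 11.0]


class TestKaplanMeier:
    def test_textbook_no_censoring(self):
        wt = WaitingTimeSet(np.array([1.0, 2.0, 3.0]), np.zeros(3, bool))
        est = km_survival(wt)
        assert est.times.tolist() == [1.0, 2.0, 3.0]
        assert np.allclose(est.S, [2 / 3, 1 / 3, 0.0])

    def test_hand_product_limit_with_censoring(self):
        wt = WaitingTimeSet(np.array([1.0, 2.0, 3.0]), np.array([False, True, False]))
        est = km_survival(wt)
        # S(1) = 2/3; the censored subject leaves the risk set; S(3) = 0
        S = dict(zip(est.times, est.S))
        assert S[1.0] == pytest.approx(2 / 3)
        assert S[3.0] == pytest.approx(0.0)

    def test_equals_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(0)
        x = rng.exponential(9.0, size=500)
        wt = WaitingTimeSet(x, np.zeros(x.size, bool))
        est = km_survival(wt)
        xs = np.sort(x)
        empirical = 1.0 - np.arange(1, x.size + 1) / x.size
        assert np.allclose(est.S, empirical, atol=1e-12)

    def test_all_censored_rejected(self):
        wt = WaitingTimeSet(np.array([1.0, 2.0]), np.array([True, True]))
        with pytest.raises(ValueError):
            km_survival(wt)

    def test_band_covers_true_exponential(self):
        rng = np.random.default_rng(1)
        x = rng.exponential(9.0, size=10_000)
        wt = WaitingTimeSet(x, np.zeros(x.size, bool))
        est = km_survival(wt)
        S_true = np.exp(-est.times / 9.0)
        inside = (S_true >= est.ci_lower) & (S_true <= est.ci_upper)
        assert inside.mean() > 0.9

    def test_band_is_ordered_and_clipped(self):
        rng = np.random.default_rng(2)
        x = rng.exponential(5.0, size=200)
        est = km_survival(WaitingTimeSet(x, np.zeros(x.size, bool)))
        assert np.all(est.ci_lower >= 0) and np.all(est.ci_upper <= 1)
        assert np.all(est.ci_lower <= est.S + 1e-12)
        assert np.all(est.S <= est.ci_upper + 1e-12)
        assert np.all(np.diff(est.S) <= 1e-12)


class TestTraceStats:
    def test_zero_trace_zero_integral(self):
        assert integral_amplitude(_trace(np.zeros(10))) == 0.0

    def test_constant_trace_integral(self):
        tr = FluorescenceTrace(0, np.arange(0.0, 101.0, 1.0), np.full(101, 2.0))
        assert integral_amplitude(tr) == pytest.approx(200.0)

    def test_single_kernel_integral(self, kernel):
        train = InitiationEventTrain(0, np.array([0.0]), (0.0, 200.0))
        from burstkin import convolve_events

        tr = convolve_events(train, kernel, frame_interval=0.1)
        assert integral_amplitude(tr, t_max=200.0) == pytest.approx(kernel.integral, rel=1e-3)

    def test_t50_all_at_ten_minutes(self):
        _, _, t50 = activation_stats([600.0] * 10)
        assert t50 == 600.0

    def test_t50_half_activate(self):
        _, _, t50 = activation_stats([300.0] * 5 + [None] * 5)
        assert t50 == 300.0

    def test_t50_undefined_below_half(self):
        _, frac, t50 = activation_stats([60.0] * 4 + [None] * 6)
        assert t50 is None
        assert frac.max() == pytest.approx(0.4)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            activation_stats([])
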