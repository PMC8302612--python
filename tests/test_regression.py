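"""Multiexponential survival regression and model selection."""

import numpy as np
import pytest

from burstkin import (
    FitConfig,
    MultiExpParams,
    MultiExponentialSurvival,
    WaitingTimeSet,
    fit_constrained_obligatory,
    fit_multiexp,
    km_survival,
    modified_ks_test,
    objective,
    select_num_states,
)
from burstkin.regression import accept_fit_params, error_intervals
from burstkin.survival import SurvivalEstimate

FAST = FitConfig(n_starts=10, seed=0)


def _surv_from(params: MultiExpParams, n: int, seed: int) -> tuple:
    rng = np.random.default_rng(seed)
    x = params.sample(n, rng)
    wt = WaitingTimeSet(x, np.zeros(x.size, bool))
    return wt, km_survival(wt)


def _fake_surv(times, S):
    times = np.asarray(times, dtype=float)
    S = np.asarray(S, dtype=float)
    return SurvivalEstimate(
        times=times,
        S=S,
        ci_lower=np.clip(S - 0.05, 0, 1),
        ci_upper=np.clip(S + 0.05, 0, 1),
        n_at_risk=np.full(times.size, 1000.0),
        n_events=times.size,
    )


class TestObjective:
    def test_zero_for_exact_params(self, sna_params):
        t = np.linspace(1, 300, 50)
        surv = _fake_surv(t, sna_params.survival(t))
        assert objective(sna_params, surv) == pytest.approx(0.0, abs=1e-24)

    def test_hand_computed_single_point(self):
        params = MultiExpParams((1.0,), (-np.log(2.0),))  # S(1) = 0.5
        surv = _fake_surv([1.0], [0.25])
        # 0.6 * (0.5-0.25)^2 + 0.4 * ln(2)^2
        expect = 0.6 * 0.0625 + 0.4 * np.log(2.0) ** 2
        assert objective(params, surv, alpha=0.6) == pytest.approx(expect, rel=1e-12)

    def test_alpha_one_is_linear_mse(self):
        params = MultiExpParams((1.0,), (-0.1,))
        t = np.array([1.0, 5.0, 10.0])
        S_e = np.array([0.8, 0.5, 0.3])
        surv = _fake_surv(t, S_e)
        expect = np.mean((params.survival(t) - S_e) ** 2)
        assert objective(params, surv, alpha=1.0) == pytest.approx(expect)

    def test_invariant_to_component_permutation(self):
        a = MultiExpParams((0.3, 0.7), (-0.01, -0.2))
        b = MultiExpParams((0.7, 0.3), (-0.2, -0.01))
        t = np.linspace(1, 100, 30)
        surv = _fake_surv(t, np.exp(-t / 20))
        assert objective(a, surv) == pytest.approx(objective(b, surv), rel=1e-12)


class TestFit:
    def test_recovers_known_biexponential(self, sna_params):
        _, surv = _surv_from(sna_params, 100_000, 1)
        fit = fit_multiexp(surv, 2, FAST)
        assert np.allclose(fit.best.exponents, sna_params.exponents, rtol=0.05)
        assert np.allclose(fit.best.amplitudes, sna_params.amplitudes, atol=0.05)

    def test_single_exponential_truth_is_degenerate_n2(self):
        mono = MultiExpParams((1.0,), (-1.0 / 9.0,))
        _, surv = _surv_from(mono, 20_000, 2)
        fit = fit_multiexp(surv, 2, FAST)
        lam = np.asarray(fit.best.exponents)
        A = np.asarray(fit.best.amplitudes)
        nearly_equal = np.isclose(lam[0], lam[1], rtol=0.15)
        tiny_amp = A.min() < 0.05
        assert nearly_equal or tiny_amp

    def test_seed_determinism(self, sna_params):
        _, surv = _surv_from(sna_params, 5_000, 3)
        a = fit_multiexp(surv, 2, FitConfig(n_starts=8, seed=5))
        b = fit_multiexp(surv, 2, FitConfig(n_starts=8, seed=5))
        assert a.best == b.best

    def test_suboptimal_objectives_ordered(self, pause_params):
        _, surv = _surv_from(pause_params, 10_000, 4)
        fit = fit_multiexp(surv, 3, FAST)
        objs = [o for _, o in fit.suboptimal]
        assert all(o >= fit.objective - 1e-15 for o in objs)


class TestAcceptance:
    def test_exact_params_usually_accepted(self, sna_params):
        # the generating parameters pass the band check in the typical
        # replicate; occasional correlated excursions of the KM path can
        # fail single seeds, so assert over a fixed panel
        hits = 0
        for seed in range(1, 11):
            _, surv = _surv_from(sna_params, 20_000, seed)
            hits += accept_fit_params(sna_params, surv)
        assert hits >= 7

    def test_biexponential_rejected_on_three_state_data(self, pause_params):
        _, surv = _surv_from(pause_params, 10_000, 6)
        fit = fit_multiexp(surv, 2, FAST)
        assert not fit.accepted

    def test_empty_grid_rejected(self, sna_params):
        surv = _fake_surv([1.0, 2.0], [0.9, 0.8])
        with pytest.raises(ValueError):
            accept_fit_params(sna_params, surv, ks_cutoff=100.0)


class TestSelection:
    def test_two_state_data_selects_two(self, sna_params):
        _, surv = _surv_from(sna_params, 10_000, 7)
        fit = select_num_states(surv, FAST)
        assert fit.best.n_exp == 2

    def test_three_state_data_selects_three(self, pause_params):
        _, surv = _surv_from(pause_params, 10_000, 8)
        fit = select_num_states(surv, FAST)
        assert fit.best.n_exp == 3

    def test_poisson_data_accepts_n2(self):
        mono = MultiExpParams((1.0,), (-1.0 / 9.0,))
        _, surv = _surv_from(mono, 10_000, 9)
        fit = select_num_states(surv, FAST)
        assert fit.best.n_exp == 2


class TestConstrained:
    def test_manifold_residual_is_zero(self, pause_params):
        _, surv = _surv_from(pause_params, 5_000, 10)
        fit = fit_constrained_obligatory(surv, FAST)
        resid = float(np.dot(fit.best.amplitudes, fit.best.exponents))
        assert abs(resid) < 1e-9

    def test_rejected_on_non_obligatory_data(self, pause_params):
        _, surv = _surv_from(pause_params, 10_000, 11)
        fit = fit_constrained_obligatory(surv, FAST)
        assert not fit.accepted

    def test_accepted_on_obligatory_type_data(self):
        # delays with zero density at t=0: an exponential stage in series
        # with a two-exponential mixture stage lies on the constraint
        # manifold by construction
        rng = np.random.default_rng(12)
        n = 10_000
        stage1 = rng.exponential(8.0, n)
        mix = rng.random(n) < 0.3
        stage2 = np.where(mix, rng.exponential(60.0, n), rng.exponential(15.0, n))
        x = stage1 + stage2
        wt = WaitingTimeSet(x, np.zeros(n, bool))
        fit = fit_constrained_obligatory(km_survival(wt), FitConfig(n_starts=20, seed=1))
        assert fit.accepted

    def test_constrained_objective_not_below_unconstrained(self, pause_params):
        _, surv = _surv_from(pause_params, 5_000, 13)
        con = fit_constrained_obligatory(surv, FAST)
        un = fit_multiexp(surv, 3, FAST)
        assert con.objective >= un.objective - 1e-12


class TestModifiedKS:
    def test_p_large_for_matching_distribution(self, sna_params):
        wt, _ = _surv_from(sna_params, 5_000, 14)
        p = modified_ks_test(wt, sna_params, cutoff=10.0)
        assert p > 0.01

    def test_p_small_for_wrong_model(self, sna_params, pause_params):
        wt, _ = _surv_from(pause_params, 10_000, 15)
        p = modified_ks_test(wt, sna_params, cutoff=10.0)
        assert p < 0.01

    def test_p_roughly_uniform_under_null(self, sna_params):
        ps = []
        for seed in range(40):
            wt, _ = _surv_from(sna_params, 800, 100 + seed)
            ps.append(modified_ks_test(wt, sna_params, cutoff=10.0))
        frac_small = np.mean(np.asarray(ps) < 0.05)
        # one-sided binomial slack around the nominal 5%
        assert frac_small <= 0.20

    def test_cutoff_beyond_data_rejected(self, sna_params):
        wt, _ = _surv_from(sna_params, 100, 16)
        with pytest.raises(ValueError):
            modified_ks_test(wt, sna_params, cutoff=float(wt.values.max() + 1))


class TestErrorIntervals:
    def test_single_solution_degenerate(self, sna_params):
        from burstkin.regression import MultiExpFit

        fit = MultiExpFit(best=sna_params, objective=1e-6, suboptimal=((sna_params, 1e-6),), accepted=True)
        iv = error_intervals(fit, overflow_ratio=2.0)
        for lo, hi in iv.values():
            assert lo == hi

    def test_infinite_ratio_envelopes_all_optima(self, sna_params):
        other = MultiExpParams((0.2, 0.8), (-0.01, -0.3))
        from burstkin.regression import MultiExpFit

        fit = MultiExpFit(
            best=sna_params,
            objective=1e-6,
            suboptimal=((sna_params, 1e-6), (other, 5.0)),
            accepted=True,
        )
        iv = error_intervals(fit, overflow_ratio=1e12)
        assert iv["lambda1"][0] <= min(sna_params.exponents[0], other.exponents[0])
        assert iv["A1"][1] >= max(sna_params.amplitudes[0], other.amplitudes[0])

    def test_intervals_contain_best(self, pause_params):
        _, surv = _surv_from(pause_params, 5_000, 17)
        fit = fit_multiexp(surv, 3, FAST)
        for i in range(3):
            lo, hi = fit.error_intervals[f"lambda{i + 1}"]
            assert lo - 1e-12 <= fit.best.exponents[i] <= hi + 1e-12


class TestEstimatorInterface:
    def test_sklearn_params_round_trip(self):
        est = MultiExponentialSurvival(alpha=0.7, n_starts=5)
        cloned = MultiExponentialSurvival(**est.get_params())
        assert cloned.get_params() == est.get_params()

    def test_fit_sets_attributes(self, sna_params):
        rng = np.random.default_rng(18)
        x = sna_params.sample(5_000, rng)
        est = MultiExponentialSurvival(n_components=2, n_starts=8, random_state=0).fit(x)
        assert est.n_components_ == 2
        assert est.accepted_ in (True, False)
        assert est.predict_survival([0.0]) == pytest.approx(1.0)
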