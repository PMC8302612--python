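"""Closed-form inversion: moment sums, rate recovery, reports."""

import numpy as np
import pytest

from burstkin import (
    MultiExpParams,
    build_model,
    derived_kinetics,
    forward_distribution,
    invert_three_state,
    invert_two_state,
    kinetics_report,
    moment_sums,
)
from burstkin.regression import MultiExpFit


def _random_model(rng, n_states):
    k = np.exp(rng.uniform(np.log(1e-3), np.log(1.0), size=5))
    if n_states == 2:
        return build_model(k1_plus=k[0], k1_minus=k[1], k_ini=k[2])
    return build_model(k1_plus=k[0], k1_minus=k[1], k_ini=k[2], k2_plus=k[3], k2_minus=k[4])


class TestMomentSums:
    def test_trivial_point_mass(self):
        params = MultiExpParams((1.0, 0.0), (-1.0, -2.0))
        m = moment_sums(params)
        assert (m.S1, m.S2, m.S3) == (-1.0, 1.0, -1.0)

    def test_first_moment_of_fast_two_state(self, sna_params):
        assert moment_sums(sna_params).S1 == pytest.approx(-1.0 / 9.0, rel=1e-12)

    def test_matches_direct_summation(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            A = rng.dirichlet([1, 1, 1])
            lam = -np.sort(np.exp(rng.uniform(-5, 0, 3)))[::-1]
            params = MultiExpParams(tuple(A), tuple(lam))
            m = moment_sums(params)
            A = np.asarray(params.amplitudes)
            lam = np.asarray(params.exponents)
            assert m.S2 == pytest.approx(float(np.sum(A * lam**2)), abs=1e-12)
            assert m.L3 == pytest.approx(float(np.sum(lam**3)), abs=1e-12)


class TestTwoStateInversion:
    def test_fast_two_state_recovery(self, sna_model, sna_params):
        r = invert_two_state(sna_params)
        assert r.valid
        assert r.k1_plus == pytest.approx(sna_model.k1_plus, rel=1e-9)
        assert r.k1_minus == pytest.approx(sna_model.k1_minus, rel=1e-9)
        assert r.k_ini == pytest.approx(sna_model.k_ini, rel=1e-9)

    def test_round_trip_random_models(self):
        # the central correctness oracle: forward then invert is identity
        rng = np.random.default_rng(1)
        for _ in range(1000):
            m = _random_model(rng, 2)
            r = invert_two_state(forward_distribution(m))
            assert r.valid
            assert r.k1_plus == pytest.approx(m.k1_plus, rel=1e-6)
            assert r.k1_minus == pytest.approx(m.k1_minus, rel=1e-6)
            assert r.k_ini == pytest.approx(m.k_ini, rel=1e-6)

    def test_positive_first_moment_invalid(self):
        # S1 > 0 would mean a negative initiation rate
        params = MultiExpParams.__new__(MultiExpParams)
        object.__setattr__(params, "amplitudes", (2.0, -1.0))
        object.__setattr__(params, "exponents", (-0.01, -1.0))
        r = invert_two_state(params)
        assert not r.valid


class TestThreeStateInversion:
    def test_round_trip_random_models(self):
        rng = np.random.default_rng(2)
        for _ in range(1000):
            m = _random_model(rng, 3)
            r = invert_three_state(forward_distribution(m))
            assert r.valid
            got = sorted([(r.k1_plus, r.k1_minus), (r.k2_plus, r.k2_minus)])
            want = sorted([(m.k1_plus, m.k1_minus), (m.k2_plus, m.k2_minus)])
            assert np.allclose(got, want, rtol=1e-6)
            assert r.k_ini == pytest.approx(m.k_ini, rel=1e-6)

    def test_pause_label_is_longer_lived(self, pause_params):
        r = invert_three_state(pause_params)
        assert r.valid
        assert 1.0 / r.k2_plus >= 1.0 / r.k1_plus  # T_PAUSE >= T_OFF

    def test_weak_pause_collapses_to_two_state(self):
        m = build_model(k1_plus=0.05, k1_minus=0.01, k_ini=0.1, k2_plus=0.01, k2_minus=1e-7)
        r = invert_three_state(forward_distribution(m))
        assert r.valid
        assert min(r.k1_minus, r.k2_minus) < 1e-6

    def test_negative_discriminant_invalid(self):
        # amplitudes/exponents not realizable by the pause topology
        params = MultiExpParams((0.4, 0.35, 0.25), (-0.011, -0.013, -4.0))
        r = invert_three_state(params)
        if not r.valid:
            assert "ill-posed" in r.reason or "nonpositive" in r.reason
        else:  # realizable after all: round trip must then hold
            p2 = forward_distribution(r.to_model())
            assert np.allclose(p2.exponents, params.exponents, rtol=1e-6)

    def test_two_state_inversion_differs_on_truncated_three_state(self, pause_params):
        # dropping the smallest component and renormalizing, then
        # inverting as 2-state, must not silently reproduce pause rates
        A = np.asarray(pause_params.amplitudes)
        lam = np.asarray(pause_params.exponents)
        keep = np.argsort(A)[-2:]
        A2 = A[keep] / A[keep].sum()
        trunc = MultiExpParams(tuple(A2), tuple(lam[keep]))
        r2 = invert_two_state(trunc)
        r3 = invert_three_state(pause_params)
        assert not np.isclose(r2.k_ini, r3.k_ini, rtol=0.01)


class TestKineticsReport:
    def test_exact_params_zero_width_intervals(self, sna_model, sna_params):
        fit = MultiExpFit(best=sna_params, objective=1e-9, suboptimal=((sna_params, 1e-9),), accepted=True)
        rep = kinetics_report(fit)
        assert not rep.flagged
        lo, hi = rep.derived_intervals["T_ON"]
        assert lo == pytest.approx(hi)
        assert lo == pytest.approx(242.0, rel=1e-6)
        assert rep.derived.burst_size == pytest.approx(26.888, rel=1e-3)

    def test_intervals_envelope_suboptimal_solutions(self, sna_params):
        other = forward_distribution(build_model(k1_plus=1 / 30.0, k1_minus=1 / 200.0, k_ini=1 / 9.0))
        fit = MultiExpFit(
            best=sna_params,
            objective=1.0,
            suboptimal=((sna_params, 1.0), (other, 1.5)),
            accepted=True,
        )
        rep = kinetics_report(fit, overflow_ratio=2.0)
        lo, hi = rep.derived_intervals["T_ON"]
        assert lo <= 200.0 + 1e-6 and hi >= 242.0 - 1e-6

    def test_all_invalid_flagged(self):
        params = MultiExpParams.__new__(MultiExpParams)
        object.__setattr__(params, "amplitudes", (2.0, -1.0))
        object.__setattr__(params, "exponents", (-0.01, -1.0))
        fit = MultiExpFit(best=params, objective=1.0, suboptimal=((params, 1.0),), accepted=True)
        rep = kinetics_report(fit)
        assert rep.flagged
        assert rep.derived is None

    def test_derived_consistency_with_model(self, pause_model, pause_params):
        fit = MultiExpFit(best=pause_params, objective=1e-9, suboptimal=((pause_params, 1e-9),), accepted=True)
        rep = kinetics_report(fit)
        truth = derived_kinetics(pause_model)
        assert rep.derived.T_ON == pytest.approx(truth.T_ON, rel=1e-6)
        assert rep.derived.p_ON + rep.derived.p_OFF + rep.derived.p_PAUSE == pytest.approx(1.0)
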