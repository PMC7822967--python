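"""Unit and property tests for the depression/recovery model."""

import json
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad, solve_ivp

import stpfit as sp
from stpfit.model import ModelState, _pn_sequence, recovery_integral


def ode_train_oracle(protocol, params):
    """Independent oracle: continuous-time integration of dc/dt = -c/tau,
    dR/dt = k(c)(1-R) with event jumps at each pulse."""

    def rhs(t, y):
        c, r = y
        k = params.k_min_per_ms + params.delta_k_per_ms * c / (c + params.k_r_half)
        return [-c / params.tau_ca_ms, k * (1.0 - r)]

    c, r = 0.0, 1.0
    p = []
    times = protocol.pulse_times
    for i, t0 in enumerate(times):
        c += params.delta_jump
        prel = params.p_max_vm * c / (c + params.k_half)
        p.append(prel * r)
        r *= 1.0 - prel
        if i + 1 < len(times):
            sol = solve_ivp(rhs, (t0, times[i + 1]), [c, r], rtol=1e-10, atol=1e-12)
            c, r = sol.y[:, -1]
    return np.array(p)


class TestReleaseProbability:
    @pytest.mark.parametrize(
        "c, expected",
        [(0.0, 0.0), (0.69, 0.375), (1.0, 0.75 / 1.69)],
    )
    def test_values_sh(self, sh_params, c, expected):
        assert sp.release_probability(c, sh_params) == pytest.approx(expected, rel=1e-12)

    def test_monotone_and_bounded(self, sh_params):
        c = np.linspace(0, 50, 500)
        p = sp.release_probability(c, sh_params)
        assert np.all(np.diff(p) > 0)
        assert np.all((p >= 0) & (p < sh_params.p_max_vm))

    def test_negative_calcium_rejected(self, sh_params):
        with pytest.raises(ValueError):
            sp.release_probability(-0.1, sh_params)


class TestRecoveryRate:
    def test_rest_rate_is_k_min(self, sh_params, hc_params):
        assert sp.recovery_rate(0.0, sh_params) == pytest.approx(9.0e-4)
        assert sp.recovery_rate(0.0, hc_params) == pytest.approx(1.2e-3)

    def test_half_saturation(self, sh_params):
        expected = 9.0e-4 + 0.017 / 2
        assert sp.recovery_rate(1.18, sh_params) == pytest.approx(expected, rel=1e-12)

    def test_asymptote(self, hc_params):
        assert sp.recovery_rate(1e9, hc_params) == pytest.approx(1.2e-3 + 9.4e-3, rel=1e-6)

    def test_saturation_contrast_between_synapse_types(self, sh_params, hc_params):
        # at accumulated calcium (c=2) the SH synapse keeps accelerating its
        # recovery while the HC recovery function is already saturated
        assert sp.recovery_rate(2.0, sh_params) > sp.recovery_rate(2.0, hc_params)
        k_sh, k_hc = sp.recovery_rate(1.0, sh_params), sp.recovery_rate(1.0, hc_params)
        assert abs(k_sh - k_hc) / k_hc < 0.10


class TestPropagateInterval:
    def test_zero_interval_is_identity(self, sh_params):
        s = ModelState(c=1.3, r=0.4)
        assert sp.propagate_interval(s, 0.0, sh_params) == s

    def test_long_interval_reaches_rest(self, sh_params):
        out = sp.propagate_interval(ModelState(c=2.0, r=0.1), 1e7, sh_params)
        assert out.c == pytest.approx(0.0, abs=1e-12)
        assert out.r == pytest.approx(1.0, abs=1e-12)

    def test_negative_interval_rejected(self, sh_params):
        with pytest.raises(ValueError):
            sp.propagate_interval(ModelState(1.0, 1.0), -1.0, sh_params)

    def test_integral_matches_quadrature(self, sh_params):
        c0, t_int = 1.0, 50.0
        oracle, err = quad(
            lambda t: sp.recovery_rate(c0 * math.exp(-t / sh_params.tau_ca_ms), sh_params),
            0.0,
            t_int,
            epsabs=1e-14,
            epsrel=1e-12,
        )
        assert recovery_integral(c0, t_int, sh_params) == pytest.approx(oracle, rel=1e-8)

    def test_closed_form_matches_ode_on_random_draws(self, rng):
        for _ in range(100):
            params = sp.SynapseParams(
                tau_ca_ms=rng.uniform(5, 60),
                p_max_vm=rng.uniform(0.2, 1.0),
                k_half=rng.uniform(0.1, 3.0),
                k_min_per_ms=rng.uniform(1e-5, 5e-3),
                delta_k_per_ms=rng.uniform(0.0, 0.05),
                k_r_half=rng.uniform(0.05, 5.0),
            )
            state = ModelState(c=rng.uniform(0, 3), r=rng.uniform(0, 1))
            t_int = rng.uniform(0.1, 2000)
            out = sp.propagate_interval(state, t_int, params)

            def rhs(t, y):
                return [
                    -y[0] / params.tau_ca_ms,
                    sp.recovery_rate(max(y[0], 0.0), params) * (1.0 - y[1]),
                ]

            sol = solve_ivp(rhs, (0, t_int), list(state), rtol=1e-10, atol=1e-13)
            assert out.c == pytest.approx(sol.y[0, -1], rel=1e-6, abs=1e-10)
            assert out.r == pytest.approx(sol.y[1, -1], rel=1e-6)


class TestSimulateTrain:
    def test_single_pulse(self, sh_params):
        resp = sp.simulate_train(sp.StimulusProtocol((0.0,)), sh_params)
        assert resp.p[0] == pytest.approx(0.75 / 1.69, rel=1e-12)
        assert resp.c_pre[0] == 0.0 and resp.c_post[0] == 1.0 and resp.r_pre[0] == 1.0

    def test_two_pulse_matches_ode_oracle(self, sh_params, hc_params):
        for params in (sh_params, hc_params):
            proto = sp.StimulusProtocol.paired(50.0)
            resp = sp.simulate_train(proto, params)
            oracle = ode_train_oracle(proto, params)
            np.testing.assert_allclose(resp.p, oracle, rtol=1e-8)

    def test_twenty_pulse_train_matches_ode_oracle(self, sh_params):
        proto = sp.StimulusProtocol.train(20.0, 20)
        resp = sp.simulate_train(proto, sh_params)
        np.testing.assert_allclose(resp.p, ode_train_oracle(proto, sh_params), rtol=1e-7)

    def test_pure_depletion_is_monotone(self, sh_params):
        params = sh_params.with_free([27.7, 0.69, 0.0, 0.0, 1.18])
        resp = sp.simulate_train(sp.StimulusProtocol.train(20.0, 20), params)
        assert np.all(np.diff(resp.r_pre) < 0)
        assert resp.p[-1] < 0.05 * resp.p[0]

    def test_constant_recovery_closed_form_ppr(self, sh_params):
        # with delta_k = 0 the pool recovers at the constant rate k_min and
        # the two-pulse response has an exact closed form
        params = sh_params.with_free([27.7, 0.69, 2e-3, 0.0, 1.18])
        for t_int in (20.0, 100.0, 700.0):
            resp = sp.simulate_train(sp.StimulusProtocol.paired(t_int), params)
            c1 = params.delta_jump
            c2 = c1 * math.exp(-t_int / params.tau_ca_ms) + params.delta_jump
            p1 = sp.release_probability(c1, params)
            p2 = sp.release_probability(c2, params)
            r2 = 1.0 - p1 * math.exp(-params.k_min_per_ms * t_int)
            assert resp.ppr == pytest.approx(p2 * r2 / p1, abs=1e-10)

    def test_pn_sequence_agrees_with_simulate_train(self, hc_params):
        proto = sp.StimulusProtocol.train(50.0, 20)
        fast = _pn_sequence(
            proto.intervals,
            hc_params.tau_ca_ms,
            hc_params.p_max_vm,
            hc_params.k_half,
            hc_params.k_min_per_ms,
            hc_params.delta_k_per_ms,
            hc_params.k_r_half,
            hc_params.delta_jump,
        )
        np.testing.assert_allclose(fast, sp.simulate_train(proto, hc_params).p, rtol=1e-14)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        tau=st.floats(1.0, 100.0),
        pmax=st.floats(0.05, 1.0),
        khalf=st.floats(0.05, 5.0),
        kmin=st.floats(0.0, 0.01),
        dk=st.floats(0.0, 0.1),
        krhalf=st.floats(0.05, 5.0),
        freq=st.floats(0.5, 200.0),
        n=st.integers(1, 30),
    )
    def test_state_stays_physical(self, tau, pmax, khalf, kmin, dk, krhalf, freq, n):
        params = sp.SynapseParams(tau, pmax, khalf, kmin, dk, krhalf)
        resp = sp.simulate_train(sp.StimulusProtocol.train(freq, n), params)
        assert np.all((resp.p >= 0) & (resp.p <= 1))
        assert np.all((resp.r_pre >= 0) & (resp.r_pre <= 1))
        assert np.all(resp.c_pre >= 0)


class TestRecoveryCurve:
    def test_full_recovery_limit(self, sh_params, hc_params):
        for params in (sh_params, hc_params):
            assert sp.simulate_recovery_curve([1e7], params)[0] == pytest.approx(1.0, abs=1e-6)

    def test_long_interval_recovery_nearly_complete(self, sh_params):
        assert sp.simulate_recovery_curve([3000.0], sh_params)[0] > 0.90

    def test_hc_curve_monotone(self, hc_params):
        curve = sp.simulate_recovery_curve([20, 50, 100, 500, 1000, 3000], hc_params)
        assert np.all(np.diff(curve) > 0)

    def test_monotone_beyond_calcium_transient(self, sh_params, hc_params):
        # once residual calcium has decayed (> ~4 tau), recovery of the
        # pool dominates and the curve must rise toward 1 for both models
        grid = np.linspace(150, 3000, 30)
        for params in (sh_params, hc_params):
            assert np.all(np.diff(sp.simulate_recovery_curve(grid, params)) > 0)


class TestSteadyState:
    def test_postjump_calcium_closed_form(self, sh_params):
        c_ss, _, _ = sp.steady_state_response(50.0, sh_params)
        assert c_ss == pytest.approx(1.0 / (1.0 - math.exp(-20.0 / 27.7)), rel=1e-5)

    def test_matches_long_train_iteration(self, hc_params):
        _, r_ss, p_ss = sp.steady_state_response(20.0, hc_params, tol=1e-10)
        resp = sp.simulate_train(sp.StimulusProtocol.train(20.0, 500), hc_params)
        assert p_ss == pytest.approx(resp.p[-1], rel=1e-8)
        assert r_ss == pytest.approx(resp.r_pre[-1], rel=1e-8)

    def test_low_frequency_limit_is_first_pulse(self, sh_params):
        _, _, p_ss = sp.steady_state_response(1e-4, sh_params)
        p1 = sp.simulate_train(sp.StimulusProtocol((0.0,)), sh_params).p[0]
        assert p_ss == pytest.approx(p1, rel=1e-6)

    def test_fixed_point_self_consistency(self, sh_params):
        c_ss, r_ss, p_ss = sp.steady_state_response(50.0, sh_params, tol=1e-9)
        prel = sp.release_probability(c_ss, sh_params)
        nxt = sp.propagate_interval(ModelState(c=c_ss, r=r_ss * (1 - prel)), 20.0, sh_params)
        assert sp.release_probability(nxt.c + 1.0, sh_params) * nxt.r == pytest.approx(
            p_ss, rel=1e-6
        )

    def test_invalid_inputs(self, sh_params):
        with pytest.raises(ValueError):
            sp.steady_state_response(-5.0, sh_params)
        with pytest.raises(ValueError):
            sp.steady_state_response(5.0, sh_params, tol=0.0)


class TestParamsAndProtocol:
    def test_json_round_trip(self, tmp_path, sh_params):
        path = tmp_path / "p.json"
        path.write_text(json.dumps(sh_params.to_dict()))
        assert sp.load_params(path) == sh_params

    @pytest.mark.parametrize(
        "field, value",
        [("tau_ca_ms", -1.0), ("p_max_vm", 1.5), ("k_half", 0.0), ("k_min_per_ms", -1e-4),
         ("delta_jump", 0.0)],
    )
    def test_invalid_params_rejected(self, sh_params, field, value):
        d = sh_params.to_dict()
        d[field] = value
        with pytest.raises(ValueError):
            sp.SynapseParams.from_dict(d)

    def test_protocol_validation(self):
        with pytest.raises(ValueError):
            sp.StimulusProtocol(())
        with pytest.raises(ValueError):
            sp.StimulusProtocol((0.0, 0.0))
        assert sp.StimulusProtocol.train(20.0, 5).intervals == (50.0,) * 4

    def test_fold_differences_match_reported_contrast(self, sh_params, hc_params):
        fold = sp.fold_differences(sh_params, hc_params)
        assert round(fold["k_r_half"], 1) == 6.2
        assert round(fold["delta_k_per_ms"], 1) == 1.8
        assert round(fold["k_min_per_ms"], 2) == 0.75
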