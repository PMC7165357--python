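"""Steady-state simulator tests: limit-cycle correctness against an
independent fixed-step Euler oracle, conservation and flow-balance
invariants, sensitivity directions and observable extraction."""

import numpy as np
import pytest

from cardiowean import (
    CVSParameters,
    DriverConfig,
    SimulationSettings,
    simulate_to_steady_state,
    steady_state_observables,
    summarize_beat,
    summarize_ostadal,
)
from cardiowean.simulate import BeatTrace

from euler_oracle import euler_observables


def _trace(pig1, Q_d=0.0, **over):
    return simulate_to_steady_state(pig1, Q_d, settings=SimulationSettings(**over))


class TestLimitCycle:
    def test_converges_and_conserves_volume(self, pig1):
        tr = _trace(pig1)
        assert tr.converged
        total = tr.V_sh + tr.V_sa + tr.V_sv
        assert np.max(np.abs(total - pig1.SBV)) < 1e-6 * pig1.SBV

    def test_valve_flows_unidirectional(self, pig1):
        tr = _trace(pig1, Q_d=20.0)
        assert np.all(tr.Q_i >= 0)
        assert np.all(tr.Q_o >= 0)

    def test_flow_balances_over_beat(self, pig1):
        # at the periodic state each compartment's mean inflow equals its
        # mean outflow: mean Q_i = mean Q_o and mean Q_s = mean Q_o + Q_d
        for Q_d in (0.0, 20.0):
            tr = _trace(pig1, Q_d=Q_d)
            mQi = np.trapezoid(tr.Q_i, tr.t) / tr.period
            mQo = np.trapezoid(tr.Q_o, tr.t) / tr.period
            mQs = np.trapezoid(tr.Q_s, tr.t) / tr.period
            assert mQi == pytest.approx(mQo, rel=0.01)
            assert mQs == pytest.approx(mQo + Q_d, rel=0.01)

    def test_euler_oracle_agreement_pig1(self, pig1):
        tr = _trace(pig1)
        obs = summarize_beat(tr).as_array()
        y0 = np.array([tr.V_sh[0], tr.V_sa[0], tr.V_sv[0]])
        oracle = euler_observables(pig1, 0.0, y0, n_beats=3)
        assert np.all(np.abs(obs / oracle - 1.0) < 0.005)

    def test_euler_oracle_agreement_sampled_parameters(self):
        # parameter sets drawn within the identified physiologic ranges
        rng = np.random.default_rng(42)
        lo = np.array([1.15, 0.025, 0.82, 0.91, 691.0, 1.17])
        hi = np.array([2.37, 0.054, 2.03, 2.21, 1764.0, 1.69])
        for _ in range(4):
            v = lo + rng.random(6) * (hi - lo)
            p = CVSParameters(E_h=v[0], A_h=v[1], E_a=v[2], R_s=v[3],
                              SBV=v[4], HR=v[5])
            tr = simulate_to_steady_state(p, 0.0)
            obs = summarize_beat(tr).as_array()
            y0 = np.array([tr.V_sh[0], tr.V_sa[0], tr.V_sv[0]])
            oracle = euler_observables(p, 0.0, y0, n_beats=3)
            assert np.all(np.abs(obs / oracle - 1.0) < 0.005)

    def test_initialization_independence(self, pig1):
        a = summarize_beat(_trace(pig1)).as_array()
        b = summarize_beat(_trace(
            pig1, initial_state_policy="user_supplied",
            initial_state=(0.1 * pig1.SBV, 0.6 * pig1.SBV, 0.3 * pig1.SBV))).as_array()
        assert np.all(np.abs(a / b - 1.0) < 1e-3)

    def test_plain_iteration_agrees_with_shooting(self, pig1):
        fast = summarize_beat(_trace(pig1)).as_array()
        slow = summarize_beat(_trace(pig1, accelerate=False,
                                     convergence_tol=1e-6,
                                     max_beats=2000)).as_array()
        assert np.all(np.abs(fast / slow - 1.0) < 2e-3)

    def test_determinism_bit_identical(self, pig1):
        a = summarize_beat(_trace(pig1, Q_d=10.0)).as_array()
        b = summarize_beat(_trace(pig1, Q_d=10.0)).as_array()
        assert np.array_equal(a, b)

    def test_monotone_sensitivities(self, pig1):
        base = summarize_beat(_trace(pig1)).P_a_mean
        up_rs = CVSParameters(**{**pig1.to_dict(), "R_s": pig1.R_s * 1.1})
        up_sbv = CVSParameters(**{**pig1.to_dict(), "SBV": pig1.SBV * 1.1})
        assert summarize_beat(_trace(up_rs)).P_a_mean > base
        assert summarize_beat(_trace(up_sbv)).P_a_mean > base


def _synthetic_trace(P_a=None, V_sh=None, n=501, T=0.8):
    t = np.linspace(0.0, T, n)
    z = np.zeros(n)
    P_a = z if P_a is None else P_a
    V_sh = z + 100.0 if V_sh is None else V_sh
    return BeatTrace(t=t, V_sh=V_sh, V_sa=z, V_sv=z, P_h=z, P_a=P_a, P_v=z,
                     Q_i=z, Q_o=z, Q_s=z, Q_d=0.0, period=T, converged=True,
                     beats_used=1)


class TestSummaries:
    def test_map_estimator_on_analytic_trace(self):
        T = 0.8
        t = np.linspace(0.0, T, 2001)
        tr = _synthetic_trace(P_a=80.0 + 40.0 * np.sin(np.pi * t / T) ** 2)
        y = summarize_beat(tr)
        assert y.P_a_mean == pytest.approx(120.0 / 3 + 2 * 80.0 / 3, abs=1e-6)
        assert y.PP_a == pytest.approx(40.0, abs=1e-6)

    def test_constant_arterial_pressure(self):
        tr = _synthetic_trace(P_a=np.full(501, 95.0))
        y = summarize_beat(tr)
        assert y.P_a_mean == pytest.approx(95.0)
        assert y.PP_a == 0.0

    def test_stroke_volume_from_heart_volume(self):
        t = np.linspace(0.0, 0.8, 501)
        V = 90.0 + 30.0 * np.sin(np.pi * t / 0.8) ** 2
        y = summarize_beat(_synthetic_trace(V_sh=V))
        assert y.maxV_h == pytest.approx(120.0, abs=1e-6)
        assert y.SV == pytest.approx(30.0, abs=1e-6)

    def test_empty_trace_rejected(self):
        tr = _synthetic_trace()
        tr.t = np.array([])
        with pytest.raises(ValueError):
            summarize_beat(tr)

    def test_ostadal_vector_internal_consistency(self, pig1):
        tr = _trace(pig1)
        y = summarize_ostadal(tr)
        assert y.SBP == pytest.approx(tr.P_h.max())
        i = int(np.argmax(tr.V_sh))
        assert y.EDP == pytest.approx(tr.P_h[i])
        assert y.SBP >= y.EDP
        assert y.EDV >= y.SV

    def test_trace_frame_and_true_map_diagnostic(self, pig1):
        tr = _trace(pig1)
        df = tr.to_frame()
        assert list(df.columns) == ["t", "V_sh", "V_sa", "V_sv", "P_h",
                                    "P_a", "P_v", "Q_i", "Q_o", "Q_s"]
        y = summarize_beat(tr)
        # the 1/3-2/3 estimator and the true time average are close but
        # distinct quantities on a real beat
        assert tr.P_a_time_average == pytest.approx(y.P_a_mean, rel=0.15)
        assert tr.P_a_time_average != y.P_a_mean


class TestSettingsValidation:
    def test_bad_settings_rejected(self):
        with pytest.raises(ValueError):
            SimulationSettings(max_beats=1)
        with pytest.raises(ValueError):
            SimulationSettings(convergence_tol=0.0)
        with pytest.raises(ValueError):
            SimulationSettings(initial_state_policy="user_supplied")

    def test_warm_state_rescaled_to_current_sbv(self, pig1):
        # a warm state from different parameters must not leak its total
        # volume into the new simulation
        obs, y0, _ = steady_state_observables(pig1, 0.0)
        obs2, y1, _ = steady_state_observables(pig1, 0.0, warm_state=y0 * 1.3)
        assert y1.sum() == pytest.approx(pig1.SBV, rel=1e-9)
        assert np.all(np.abs(obs2.as_array() / obs.as_array() - 1.0) < 1e-3)
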