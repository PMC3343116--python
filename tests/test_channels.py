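import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pfcpersist.channels import (
    CalciumPoolParams, CanParams, DadpMeasurement, GateParams, PassiveParams,
    SynapseSpec, calcium_pool_step, can_steady_state, dadp_amplitude_from_trace,
    default_synapse, dualexp_norm, dualexp_peak_time, mg_block, nmda_gating,
)


class TestCanSteadyState:
    def test_half_activation_at_cac(self):
        p = CanParams()
        m_inf, _ = can_steady_state(p.cac, p)
        assert m_inf == pytest.approx(0.5)

    def test_zero_calcium_limit(self):
        p = CanParams()
        m_inf, tau = can_steady_state(0.0, p)
        assert m_inf == 0.0
        assert tau == pytest.approx(1.0 / p.beta)  # 1e5 ms

    def test_twice_cac(self):
        p = CanParams()
        m_inf, _ = can_steady_state(2 * p.cac, p)
        assert m_inf == pytest.approx(4.0 / 5.0)

    def test_negative_calcium_rejected(self):
        with pytest.raises(ValueError):
            can_steady_state(-1e-5, CanParams())

    @given(c1=st.floats(0, 5e-3), c2=st.floats(0, 5e-3))
    @settings(max_examples=50, deadline=None)
    def test_monotonicity(self, c1, c2):
        p = CanParams()
        lo, hi = sorted([c1, c2])
        m1, t1 = can_steady_state(lo, p)
        m2, t2 = can_steady_state(hi, p)
        assert 0.0 <= m1 <= m2 < 1.0
        assert t1 >= t2 > 0.0


class TestCalciumPool:
    def test_equilibrium_is_fixed_point(self):
        p = CalciumPoolParams()
        assert calcium_pool_step(p.cai0, 0.0, 0.1, p) == pytest.approx(p.cai0)

    def test_relaxation_matches_analytic_exponential(self):
        p = CalciumPoolParams()
        cai = 10 * p.cai0
        dt, total = 0.5, 200.0
        for _ in range(int(total / dt)):
            cai = calcium_pool_step(cai, 0.0, dt, p)
        expected = p.cai0 + 9 * p.cai0 * math.exp(-total / p.tau)
        assert cai == pytest.approx(expected, rel=1e-9)

    def test_sustained_influx_reaches_finite_plateau(self):
        p = CalciumPoolParams()
        cai, prev = p.cai0, -1.0
        for _ in range(5000):
            prev = cai
            cai = calcium_pool_step(cai, -0.05, 1.0, p)  # inward 50 uA/cm^2
            assert cai >= prev  # monotone approach
        # plateau = cai0 + k*|i|*tau, finite
        k = p.f_buffer * 1e4 / (2 * 96485.3321 * p.depth)
        assert cai == pytest.approx(p.cai0 + k * 0.05 * p.tau, rel=1e-6)

    def test_never_below_resting_level(self):
        p = CalciumPoolParams()
        assert calcium_pool_step(p.cai0, +1.0, 1.0, p) >= p.cai0  # outward current

    def test_bad_dt_rejected(self):
        with pytest.raises(ValueError):
            calcium_pool_step(1e-4, 0.0, 0.0)


class TestNmdaGating:
    def test_mg_block_vanishes_at_strong_depolarisation(self):
        assert mg_block(100.0) == pytest.approx(1.0, abs=0.02)

    def test_mg_block_small_near_rest(self):
        assert mg_block(-70.0) < 0.1

    def test_faster_inactivation_shrinks_decay_time_tenfold(self):
        s_ctrl = default_synapse("NMDA", b_nmda=1e-2)
        s_fast = default_synapse("NMDA", b_nmda=1e-1)
        t = np.linspace(0.0, 2000.0, 40001)

        def t90(s):
            g = nmda_gating(t, 0.0, s)
            peak = g.max()
            i_pk = g.argmax()
            below = np.flatnonzero(g[i_pk:] <= 0.1 * peak)
            return t[i_pk + below[0]] - t[i_pk]

        ratio = t90(s_ctrl) / t90(s_fast)
        assert 7.0 <= ratio <= 13.0

    def test_charge_increases_when_b_nmda_decreases(self):
        t = np.linspace(0.0, 5000.0, 20001)
        q = []
        for b in (1e-1, 1e-2, 1e-3):
            g = nmda_gating(t, -20.0, default_synapse("NMDA", b_nmda=b))
            q.append(np.trapezoid(g, t))
        assert q[0] < q[1] < q[2]

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            nmda_gating(-1.0, 0.0, default_synapse("NMDA"))

    def test_dualexp_norm_gives_unit_peak(self):
        tr, td = 0.5, 3.0
        tp = dualexp_peak_time(tr, td)
        peak = dualexp_norm(tr, td) * (math.exp(-tp / td) - math.exp(-tp / tr))
        assert peak == pytest.approx(1.0)


class TestDadpFromTrace:
    def test_constructed_exponential_recovered(self):
        dt = 0.5
        t = np.arange(0, 12000.0, dt)
        base = -66.0
        v = np.full_like(t, base)
        spikes = np.array([500.0, 550.0, 600.0])
        onset = 600.0
        tail = t >= onset
        v[tail] += 3.0 * np.exp(-(t[tail] - onset) / 3000.0)
        m = dadp_amplitude_from_trace(t, v, spikes, baseline_window=(0.0, 480.0))
        assert m.amplitude == pytest.approx(3.0 * math.exp(-200.0 / 3000.0), rel=0.02)
        assert m.tau_decay == pytest.approx(3000.0, rel=0.05)
        assert m.baseline == pytest.approx(base)

    def test_window_outside_trace_raises(self):
        t = np.arange(0, 1000.0, 1.0)
        v = np.full_like(t, -66.0)
        with pytest.raises(ValueError, match="beyond trace end"):
            dadp_amplitude_from_trace(t, v, np.array([900.0]), baseline_window=(0, 500))


class TestSpecValidation:
    def test_passive_params_reject_nonpositive(self):
        with pytest.raises(ValueError):
            PassiveParams(rm=-1.0)

    def test_synapse_spec_invariants(self):
        with pytest.raises(ValueError):
            SynapseSpec("AMPA", -1.0, 0.5, 3.0, 0.0)
        with pytest.raises(ValueError):
            SynapseSpec("AMPA", 1.0, 3.0, 0.5, 0.0)  # decay must exceed rise
        with pytest.raises(ValueError):
            SynapseSpec("WEIRD", 1.0, 0.5, 3.0, 0.0)

    def test_can_params_invariants(self):
        with pytest.raises(ValueError):
            CanParams(na_fraction=1.5)
        with pytest.raises(ValueError):
            CanParams(beta=0.0)

    def test_gate_tau_is_positive_everywhere(self):
        g = GateParams(-40.0, 6.0, 0.5, 3.0, -50.0, 15.0)
        v = np.linspace(-120, 70, 500)
        assert np.all(g.tau(v) >= 0.5)
        assert np.all((g.inf(v) >= 0) & (g.inf(v) <= 1))
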