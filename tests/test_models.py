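"""Model dynamics: derivatives, conductance decay, spike detection/reset."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spikesim.models import (InvalidModelError, ModelKind, NeuronParameters,
                             NeuronState, NumericDomainError,
                             apply_input_spike, check_spike_and_reset,
                             decay_conductances, evaluate_derivatives,
                             hh_gating_steady_state, hh_rates,
                             load_parameters)
from spikesim.time_driven import rk4_step


class TestDerivatives:
    def test_lif_equilibrium(self, lif_params):
        st0 = NeuronState(V=lif_params.E_L)
        assert evaluate_derivatives("lif", lif_params, st0)["V"] == 0.0

    def test_lif_membrane_leak(self, lif_params):
        # g_L (E_L - V) / C with C=190 pF, g_L=10 nS, 5 mV below rest
        d = evaluate_derivatives("lif", lif_params, NeuronState(V=-70.0))
        assert d["V"] == pytest.approx(10.0 * 5.0 / 190.0, rel=1e-12)

    @pytest.mark.parametrize("kind", ["lif", "adex", "hh"])
    def test_conductance_decay_rates(self, kind):
        p = NeuronParameters.defaults(kind)
        s = NeuronState.resting(p)
        s.g_ampa = s.g_gaba = 3.0
        d = evaluate_derivatives(kind, p, s)
        assert d["g_ampa"] == pytest.approx(-3.0 / p.tau_AMPA)
        assert d["g_gaba"] == pytest.approx(-3.0 / p.tau_GABA)

    def test_adex_terms(self, adex_params):
        p = adex_params
        s = NeuronState(V=-55.0, w=5.0)
        d = evaluate_derivatives("adex", p, s)
        exp_term = p.g_L * p.Delta_T * math.exp((-55.0 - p.V_T) / p.Delta_T)
        expect = (p.g_L * (p.E_L + 55.0) + exp_term - 5.0) / p.C
        assert d["V"] == pytest.approx(expect, rel=1e-12)
        assert d["w"] == pytest.approx((p.a * (-55.0 - p.E_L) - 5.0)
                                       / p.tau_w, rel=1e-12)

    def test_hh_gating_at_steady_state(self, hh_params):
        s = NeuronState.resting(hh_params)
        d = evaluate_derivatives("hh", hh_params, s)
        for g in ("m", "h", "n"):
            assert abs(d[g]) < 1e-12

    def test_unknown_model_rejected(self, lif_params):
        with pytest.raises((InvalidModelError, ValueError)):
            evaluate_derivatives("izhikevich", lif_params,
                                 NeuronState(V=-65.0))

    def test_nonfinite_state_rejected(self, lif_params):
        with pytest.raises(NumericDomainError):
            evaluate_derivatives("lif", lif_params,
                                 NeuronState(V=float("nan")))

    def test_rate_functions_continuous_at_singularities(self, hh_params):
        # alpha_m, beta_m, alpha_n have removable 0/0 points; the
        # implementation must interpolate them smoothly.
        for u_sing in (13.0, 40.0, 15.0):
            V = hh_params.V_T + u_sing
            lo = np.array(hh_rates(hh_params, V - 1e-7))
            at = np.array(hh_rates(hh_params, V))
            hi = np.array(hh_rates(hh_params, V + 1e-7))
            assert np.all(np.isfinite(at))
            assert np.allclose(lo, at, rtol=1e-5)
            assert np.allclose(hi, at, rtol=1e-5)


class TestConductances:
    def test_decay_closed_form(self, lif_params):
        ga, gg = decay_conductances(lif_params, 7.0, 2.0,
                                    lif_params.tau_AMPA)
        assert ga == pytest.approx(7.0 / math.e, rel=1e-12)
        assert gg == pytest.approx(2.0 * math.exp(-5.0 / 10.0), rel=1e-12)

    def test_zero_interval_identity(self, lif_params):
        assert decay_conductances(lif_params, 4.0, 1.5, 0.0) == (4.0, 1.5)

    def test_negative_interval_rejected(self, lif_params):
        with pytest.raises(ValueError):
            decay_conductances(lif_params, 1.0, 1.0, -0.1)

    @settings(derandomize=True, max_examples=50)
    @given(g=st.floats(0.0, 100.0), dt1=st.floats(0.0, 50.0),
           dt2=st.floats(0.0, 50.0))
    def test_decay_semigroup(self, lif_params, g, dt1, dt2):
        # decaying dt1 then dt2 equals decaying dt1 + dt2
        a1, b1 = decay_conductances(lif_params, g, g, dt1)
        a2, b2 = decay_conductances(lif_params, a1, b1, dt2)
        a3, b3 = decay_conductances(lif_params, g, g, dt1 + dt2)
        assert a2 == pytest.approx(a3, rel=1e-12, abs=1e-300)
        assert b2 == pytest.approx(b3, rel=1e-12, abs=1e-300)


class TestInputSpikes:
    def test_excitatory_increment(self):
        s = apply_input_spike(NeuronState(V=-65.0), 7.0, "excitatory")
        assert s.g_ampa == 7.0 and s.g_gaba == 0.0

    def test_inhibitory_increment(self):
        s0 = NeuronState(V=-65.0, g_gaba=1.0)
        s = apply_input_spike(s0, 2.5, "inhibitory")
        assert s.g_gaba == 3.5 and s.g_ampa == 0.0
        assert s0.g_gaba == 1.0  # input untouched

    def test_zero_weight_noop(self):
        s0 = NeuronState(V=-60.0, g_ampa=2.0)
        s = apply_input_spike(s0, 0.0, "excitatory")
        assert s.g_ampa == 2.0 and s.V == -60.0

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            apply_input_spike(NeuronState(V=-65.0), -1.0, "inhibitory")


class TestSpikeDetection:
    def test_lif_below_threshold(self, lif_params):
        before = NeuronState(V=-65.0)
        after = NeuronState(V=-60.0)
        fired, out = check_spike_and_reset("lif", lif_params, before, after,
                                           10.0)
        assert not fired and out.V == -60.0

    def test_lif_fires_and_resets(self, lif_params):
        fired, out = check_spike_and_reset(
            "lif", lif_params, NeuronState(V=-55.0), NeuronState(V=-49.0),
            10.0)
        assert fired
        assert out.V == lif_params.E_L
        assert out.refractory_until == pytest.approx(12.5)  # T_ref = 2.5 ms

    def test_lif_refractory_suppression(self, lif_params):
        after = NeuronState(V=-49.0, refractory_until=11.0)
        fired, out = check_spike_and_reset(
            "lif", lif_params, NeuronState(V=-55.0), after, 10.0)
        assert not fired
        assert out.V == lif_params.E_L  # clamped while refractory

    def test_adex_reset_and_adaptation_jump(self, adex_params):
        after = NeuronState(V=-39.0, w=10.0)
        fired, out = check_spike_and_reset(
            "adex", adex_params, NeuronState(V=-45.0), after, 5.0)
        assert fired
        assert out.V == adex_params.V_r == -80.0
        assert out.w == pytest.approx(10.0 + adex_params.b)

    def test_hh_upward_crossing_only(self, hh_params):
        fired, out = check_spike_and_reset(
            "hh", hh_params, NeuronState(V=-40.0), NeuronState(V=-20.0), 3.0)
        assert fired
        assert out.V == -20.0  # no reset: the ODE shapes the spike
        assert out.refractory_until == pytest.approx(3.0 + hh_params.T_spike)
        # still above threshold later: not a new spike
        fired2, _ = check_spike_and_reset(
            "hh", hh_params, NeuronState(V=-20.0), NeuronState(V=-10.0), 3.1)
        assert not fired2


class TestRelaxationInvariants:
    @pytest.mark.parametrize("kind", ["lif", "adex"])
    def test_convergence_to_rest(self, kind):
        # with zero conductances the membrane relaxes to E_L (and w to 0)
        p = NeuronParameters.defaults(kind)
        s = NeuronState(V=-75.0, w=20.0 if kind == "adex" else 0.0)
        for _ in range(500):
            s = rk4_step(kind, p, s, 1.0)
        assert abs(s.V - p.E_L) < 0.01
        if kind == "adex":
            assert abs(s.w) < 0.01

    def test_hh_gating_bounded(self, hh_params):
        s = NeuronState.resting(hh_params)
        s.g_ampa = 30.0  # strong drive: spike and recover
        for _ in range(3000):
            s = rk4_step("hh", hh_params, s, 0.01)
            for g in (s.m, s.h, s.n):
                assert 0.0 <= g <= 1.0

    def test_conductances_nonincreasing_between_spikes(self, lif_params):
        s = NeuronState(V=-65.0, g_ampa=7.0, g_gaba=2.5)
        prev = (s.g_ampa, s.g_gaba)
        for _ in range(200):
            s = rk4_step("lif", lif_params, s, 0.5)
            assert 0.0 <= s.g_ampa <= prev[0]
            assert 0.0 <= s.g_gaba <= prev[1]
            prev = (s.g_ampa, s.g_gaba)


class TestParameterSets:
    def test_benchmark_values(self, lif_params, adex_params, hh_params):
        assert lif_params.C == 190.0 and lif_params.T_ref == 2.5
        assert lif_params.tau_AMPA == 5.0 and lif_params.tau_GABA == 10.0
        assert adex_params.Delta_T == 2.0 and adex_params.b == 9.0
        assert adex_params.V_detect == pytest.approx(-40.0)  # V_T + 5 dT
        assert hh_params.g_Kd == 6000.0 and hh_params.E_K == -90.0

    def test_invariant_validation(self):
        with pytest.raises(ValueError):
            NeuronParameters.lif(C=-1.0)
        with pytest.raises(ValueError):
            NeuronParameters.adex(Delta_T=0.0)
        with pytest.raises(ValueError):
            NeuronParameters.lif(tau_AMPA=0.0)

    def test_loader_converts_si_units(self, tmp_path):
        f = tmp_path / "lif.json"
        f.write_text('{"model": "lif",'
                     '"C": {"value": 0.19e-9, "unit": "F"},'
                     '"E_L": {"value": -0.065, "unit": "V"},'
                     '"g_L": {"value": 10e-9, "unit": "S"},'
                     '"V_T": {"value": -0.050, "unit": "V"},'
                     '"T_ref": {"value": 0.0025, "unit": "s"},'
                     '"tau_AMPA": {"value": 0.005, "unit": "s"}}')
        p = load_parameters(f)
        assert p.kind is ModelKind.LIF
        assert p.C == pytest.approx(190.0)
        assert p.E_L == pytest.approx(-65.0)
        assert p.g_L == pytest.approx(10.0)
        assert p.V_T == pytest.approx(-50.0)
        assert p.T_ref == pytest.approx(2.5)
        assert p.tau_AMPA == pytest.approx(5.0)

    def test_loader_rejects_unknown_key(self, tmp_path):
        f = tmp_path / "bad.json"
        f.write_text('{"model": "lif", "frobnicate": 3}')
        with pytest.raises(ValueError):
            load_parameters(f)

    def test_hh_steady_state_is_rate_balance(self, hh_params):
        m, h, n = hh_gating_steady_state(hh_params, -65.0)
        a_m, b_m, a_h, b_h, a_n, b_n = hh_rates(hh_params, -65.0)
        assert m == pytest.approx(a_m / (a_m + b_m))
        assert h == pytest.approx(a_h / (a_h + b_h))
        assert n == pytest.approx(a_n / (a_n + b_n))
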