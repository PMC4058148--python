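"""Exogenous chelator kinetics, dialysis and shuttle diagnostics."""

import numpy as np
import pytest
from hypothesis import given, settings as hsettings, strategies as st

import dyadca as d
from dyadca.buffers import buffer_reaction_rate, dialysis_flux
from dyadca.fixtures import gen_buffer_relaxation
from dyadca.params import ParameterError


class TestReactionRate:
    def test_no_buffer_no_rate(self):
        assert buffer_reaction_rate(0.5, 0.0, 0.0, 5000.0, 0.75) == 0.0

    def test_detailed_balance_at_equilibrium(self):
        k_on, k_off = 5000.0, 0.75
        ca, b_free = 1.0e-4, 2.0
        b_bound = k_on * ca * b_free / k_off
        assert buffer_reaction_rate(ca, b_free, b_bound, k_on, k_off) == \
            pytest.approx(0.0, abs=1e-12)

    def test_negative_input_rejected(self):
        with pytest.raises(ParameterError):
            buffer_reaction_rate(-1.0, 1.0, 0.0, 5000.0, 0.75)

    @given(ca=st.floats(0, 1), bf=st.floats(0, 10), bb=st.floats(0, 10))
    @hsettings(max_examples=100, deadline=None, derandomize=True)
    def test_sign_structure(self, ca, bf, bb):
        # formation positive when association dominates, negative otherwise
        rate = buffer_reaction_rate(ca, bf, bb, 5000.0, 0.75)
        assert rate == pytest.approx(5000.0 * ca * bf - 0.75 * bb)

    def test_pseudo_first_order_relaxation_oracle(self):
        """At clamped Ca, bound buffer approaches equilibrium
        mono-exponentially at rate k_on*ca + k_off (closed-form oracle)."""
        sys_ = gen_buffer_relaxation(ca_fixed=1.0e-3, b_total=5.0,
                                     k_on=5000.0, k_off=0.75)
        t_end = 5.0 / sys_.params["rate"]
        t, y = sys_.integrate(t_end, rtol=1e-12, atol=1e-14)
        ref = sys_.closed_form(t)
        err = np.max(np.abs(y - ref)) / np.max(np.abs(ref))
        assert err < 1e-8


class TestDialysis:
    def test_equal_concentrations_no_flux(self):
        assert dialysis_flux(3.0, 3.0, 10.0) == 0.0

    def test_first_order_toward_pipette(self):
        assert dialysis_flux(0.0, 10.0, 5.0) == pytest.approx(2.0)

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(ParameterError):
            dialysis_flux(1.0, 0.0, 0.0)

    def test_monoexponential_equilibration_closed_form(self):
        from scipy.integrate import solve_ivp
        tau, target = 12.0, 10.0
        sol = solve_ivp(lambda t, y: [dialysis_flux(y[0], target, tau)],
                        (0, 60.0), [0.0], rtol=1e-10, atol=1e-12,
                        t_eval=np.linspace(0, 60, 31))
        ref = target * (1.0 - np.exp(-sol.t / tau))
        assert np.allclose(sol.y[0], ref, rtol=1e-7, atol=1e-9)


class TestPresets:
    def test_on_rates(self):
        assert d.egta().k_on == 5000.0
        assert d.bapta().k_on == 500000.0
        # 100-fold on-rate separation is the slow/fast shuttle distinction
        assert d.bapta().k_on / d.egta().k_on == 100.0

    def test_dissociation_constants_pinned(self):
        assert d.egta().kd == pytest.approx(1.5e-4)
        assert d.bapta().kd == pytest.approx(2.0e-4)

    def test_zero_concentration_is_disabled(self):
        assert not d.make_buffer("egta", 0.0).enabled
        assert not d.NONE.enabled

    def test_pipette_partition_conserves_total(self):
        buf = d.bapta(10.0)
        free, bound = buf.pipette_partition()
        assert free + bound == pytest.approx(10.0)
        assert bound / (free * buf.ca_pipette) == pytest.approx(1 / buf.kd)

    def test_unknown_preset_rejected(self):
        with pytest.raises(ParameterError):
            d.make_buffer("quin2")


class TestShuttleDiagnostics:
    def test_uniform_buffer_at_rest_gives_zero(self, params, settings):
        """Pre-stimulus steady state with uniform buffer: both gradient
        signals are identically zero."""
        from dyadca.engine import integrate_cycle
        buf = d.egta(5.0)
        ic = {}
        for c in ("c", "ss", "st", "ds", "dt"):
            ic[f"bext_free_{c}"] = 4.0
            ic[f"bext_ca_{c}"] = 1.0
        s = d.assemble_state(params, ic)
        # zero-amplitude stimulus: no AP, buffer stays uniform
        prot = d.make_current_clamp(5.0, 600.0, stim_amplitude=1e-30)
        tr = integrate_cycle(params, d.CONTROL, buf, prot, settings, s.y)
        diag = d.shuttle_diagnostics(tr)
        # the shipped initial state is end-diastolic, not an exact fixed
        # point, so allow drift-level gradients (1e-5 mM on a 5 mM buffer
        # vs ~1e-2 mM gradients during a stimulated transient)
        assert np.max(np.abs(diag.delta_bound_t)) < 2e-5
        assert np.max(np.abs(diag.delta_free_t)) < 2e-5

    def test_missing_species_raises(self, control_5hz):
        # control trace has the columns but a crafted object does not
        class Dummy:
            columns = ("ca_c",)
        with pytest.raises(KeyError):
            d.shuttle_diagnostics(Dummy())

    def test_bapta_gradients_exceed_egta(self, egta10_1hz, bapta10_1hz):
        """Fast binding -> larger free and Ca-bound buffer gradients between
        dyad and subsarcolemmal space (the fast-shuttle signature)."""
        ge = d.shuttle_diagnostics(egta10_1hz.cycle)
        gb = d.shuttle_diagnostics(bapta10_1hz.cycle)
        assert np.max(np.abs(gb.delta_bound_t)) > np.max(np.abs(ge.delta_bound_t))
        assert np.max(np.abs(gb.delta_free_t)) > np.max(np.abs(ge.delta_free_t))
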