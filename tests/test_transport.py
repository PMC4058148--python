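"""Membrane currents, SR fluxes, CDI behaviour and the accelerated kernel."""

import numpy as np
import pytest

import dyadca as d
from dyadca.engine import _Ctx, _rhs_py
from dyadca._kernel import rhs_kernel
from dyadca.params import ParameterError
from dyadca.protocols import K_CURRENTS, make_current_clamp, make_voltage_clamp_train
from dyadca.transport import serca_flux, cicr_release, gate_inf, gate_tau


class TestSercaFlux:
    def test_zero_density_zero_flux(self, params):
        assert serca_flux(1e-3, 1.0, 0.0, params) == 0.0

    def test_linear_in_density(self, params):
        j1 = serca_flux(1e-3, 1.0, 0.25, params)
        j2 = serca_flux(1e-3, 1.0, 0.5, params)
        assert j2 == pytest.approx(2 * j1)

    def test_monotone_in_local_ca_grid_oracle(self, params):
        # brute-force sign check of finite differences over a wide grid
        grid = np.logspace(-6, 0, 80)
        vals = [serca_flux(ca, 1.0, 1.0, params) for ca in grid]
        assert np.all(np.diff(vals) > 0)

    def test_reverses_when_lumen_saturation_dominates(self, params):
        # thermodynamic backflux: empty cytosol + loaded SR pumps backwards
        assert serca_flux(1e-6, 3.0, 1.0, params) < 0

    def test_negative_concentration_rejected(self, params):
        with pytest.raises(ParameterError):
            serca_flux(-1e-3, 1.0, 1.0, params)

    def test_out_of_range_density_rejected(self, params):
        with pytest.raises(ParameterError):
            serca_flux(1e-3, 1.0, 1.5, params)


class TestCICR:
    def test_empty_jsr_releases_nothing(self, params):
        assert cicr_release(1e-4, 0.0, (1.0, 1.0), params) == 0.0

    def test_closed_trigger_releases_nothing(self, params):
        assert cicr_release(1e-4, 1.0, (0.0, 1.0), params) == 0.0

    def test_release_nonnegative_and_gradient_driven(self, params):
        lo = cicr_release(1e-4, 0.5, (0.5, 0.9), params)
        hi = cicr_release(1e-4, 1.0, (0.5, 0.9), params)
        assert 0 < lo < hi

    def test_activation_gate_speeds_with_trigger_amplitude(self, params):
        # faster early dyadic Ca rise -> larger activation steady state
        o_small = gate_inf("ryr_o_t", -80, 1e-3, params)
        o_big = gate_inf("ryr_o_t", -80, 0.2, params)
        assert o_big > o_small


class TestComputeCurrents:
    def test_no_dyadic_ncx_in_control(self, params):
        s = d.assemble_state(params)
        cur = d.compute_currents(s, -80.0, params, d.CONTROL)
        assert cur.i_naca_dt == 0.0 and cur.i_naca_ds == 0.0

    def test_k_currents_exactly_zero_when_disabled(self, params):
        s = d.assemble_state(params)
        cur = d.compute_currents(s, 0.0, params, d.CONTROL,
                                 disabled=frozenset(K_CURRENTS))
        assert cur.i_kto == 0.0 and cur.i_kss == 0.0
        assert cur.i_k1 == 0.0 and cur.i_kb == 0.0 and cur.i_f == 0.0

    def test_site_components_sum_to_whole_cell(self, params):
        s = d.assemble_state(params, {"ca_dt": 1e-3})
        dist = d.DistributionFractions(0.3, 0.3, 0.3, 1.0)
        cur = d.compute_currents(s, -20.0, params, dist)
        assert cur.i_naca == pytest.approx(
            cur.i_naca_dt + cur.i_naca_ds + cur.i_naca_st + cur.i_naca_ss)
        assert cur.j_up == pytest.approx(
            cur.j_up_c + cur.j_up_dt + cur.j_up_ds)

    def test_invalid_distribution_rejected(self, params):
        with pytest.raises(ParameterError):
            d.DistributionFractions(f_up_d=2.0)

    def test_cdi_gate_monotone_decreasing_in_local_ca(self, params):
        cas = np.logspace(-5, 0, 50)
        infs = [gate_inf("fca_t", 0.0, ca, params) for ca in cas]
        assert np.all(np.diff(infs) < 0)
        assert 0 <= infs[-1] <= infs[0] <= 1

    def test_gate_taus_positive(self, params):
        for g in ("m", "h", "j", "d", "f", "fca_t", "ryr_o_t", "ryr_a_t"):
            for v in (-90.0, -40.0, 0.0, 40.0):
                assert gate_tau(g, v, params) > 0


class TestChargeBookkeeping:
    def test_dvdt_is_total_current_over_capacitance(self, params):
        """Under current clamp dV/dt = -(sum of membrane currents + stim)/Cm."""
        prot = make_current_clamp(5.0, 600.0)
        ctx = _Ctx(params, d.CONTROL, d.NONE, prot)
        s = d.assemble_state(params)
        stim = float(params.get("stimulus.amplitude"))
        dy = _rhs_py(0.0, s.y, ctx, stim, None)
        cur = d.compute_currents(s, s["v"], params, d.CONTROL, i_stim=stim)
        assert dy[0] == pytest.approx(-(cur.i_membrane + stim) / params.cm)

    def test_voltage_clamp_pins_potential(self, params):
        prot = make_voltage_clamp_train()
        ctx = _Ctx(params, d.CONTROL, d.NONE, prot)
        s = d.assemble_state(params)
        dy = _rhs_py(0.0, s.y, ctx, 0.0, 0.0)
        assert dy[0] == 0.0


class TestKernelConsistency:
    """The numba kernel is a transcription of the reference implementation;
    they must agree to machine precision over representative states."""

    @pytest.mark.parametrize("with_buffer", [False, True])
    @pytest.mark.parametrize("vclamp", [False, True])
    def test_kernel_matches_reference(self, params, with_buffer, vclamp):
        buf = d.bapta(10.0) if with_buffer else d.NONE
        prot = make_voltage_clamp_train() if vclamp \
            else make_current_clamp(5.0, 600.0, dialysis=with_buffer)
        dist = d.DistributionFractions(0.2, 0.1, 0.3, 1.0)
        ctx = _Ctx(params, dist, buf, prot)
        rng = np.random.default_rng(42)
        base = d.assemble_state(params).y
        for _ in range(6):
            y = base * (0.5 + rng.random(d.N_STATES))
            y[0] = -90 + 140 * rng.random()
            vcmd = 0.0 if vclamp else None
            dk = rhs_kernel(0.0, y, ctx.pp, -4e-6, 0.0 if vcmd is None else vcmd,
                            vcmd is not None)
            dp = _rhs_py(0.0, y, ctx, -4e-6, vcmd)
            np.testing.assert_allclose(dk, dp, rtol=5e-13, atol=1e-300)
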