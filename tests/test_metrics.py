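"""Cycle metrics against analytic toy-trace ground truth."""

import numpy as np
import pytest

import dyadca as d
from dyadca.fixtures import (gen_triangular_ap, gen_exponential_ica,
                             gen_rectangular_flux)
from dyadca.metrics import (apd50, t037, n_ca, percent_change,
                            NoActionPotential)
from dyadca.constants import FARADAY


class _VTrace:
    """Minimal trace shim carrying a voltage waveform."""

    def __init__(self, time, v):
        self.time = time
        self.v = v


class TestAPD50:
    def test_triangular_ap_geometry_oracle(self):
        toy = gen_triangular_ap(v_rest=-80.0, v_peak=40.0,
                                t_upstroke=1.0e-3, t_repol=0.1)
        value = apd50(_VTrace(toy.time, toy.v))
        assert value == pytest.approx(toy.truth["apd50_ms"], abs=0.2)

    def test_flat_trace_reports_no_ap(self):
        t = np.linspace(0, 0.2, 500)
        with pytest.raises(NoActionPotential):
            apd50(_VTrace(t, np.full_like(t, -80.0)))


class TestT037:
    def test_exponential_decay_tau_20ms(self):
        # literal 0.37 crossing of exp decay: -tau*ln(0.37) = 19.885 ms
        toy = gen_exponential_ica(tau=0.02)
        value, censored = t037(toy.time, toy.ica)
        assert not censored
        assert value == pytest.approx(toy.truth["t037_ms"], abs=0.05)
        assert value == pytest.approx(-0.02 * np.log(0.37) * 1e3, abs=0.05)

    def test_censored_when_decay_incomplete(self):
        toy = gen_exponential_ica(tau=2.0, t_total=0.2)
        value, censored = t037(toy.time, toy.ica)
        assert censored
        assert value == pytest.approx(200.0, abs=1.0)

    def test_coarse_sampling_interpolates(self):
        """Interpolated crossing on a coarse grid matches the fine-grid
        crossing within one coarse step (resampling oracle)."""
        fine = gen_exponential_ica(tau=0.02, dt=1.0e-5)
        coarse = gen_exponential_ica(tau=0.02, dt=2.0e-3)
        v_fine, _ = t037(fine.time, fine.ica)
        v_coarse, _ = t037(coarse.time, coarse.ica)
        assert abs(v_fine - v_coarse) < 2.0  # ms, one coarse step


class TestNCa:
    def test_zero_flux_zero_moles(self):
        t = np.linspace(0, 1, 100)
        assert n_ca(t, np.zeros_like(t), "naca") == 0.0

    def test_rectangular_pulse_amplitude_times_width(self):
        toy = gen_rectangular_flux(amplitude=1.0, width=0.1)
        # raw integral of the waveform equals a*w
        integral = np.trapezoid(toy.flux, toy.time)
        assert integral == pytest.approx(toy.truth["integral"], rel=1e-3)
        # channel conversion: rectangular inward divalent current
        fmol = n_ca(toy.time, -toy.flux * 1e-6, "ca")
        expected = 1e-6 * 0.1 * 1e-3 / (2 * FARADAY) * 1e12
        assert fmol == pytest.approx(expected, rel=1e-3)

    def test_sign_conventions(self):
        t = np.linspace(0, 1, 1000)
        inward = np.full_like(t, -1e-6)  # inward current
        assert n_ca(t, inward, "ca") > 0       # Ca entry positive for I_Ca
        assert n_ca(t, inward, "naca") > 0     # inward NCX = extrusion positive
        outward = -inward
        assert n_ca(t, outward, "pca") > 0     # outward pump = extrusion

    def test_up_kind_requires_params(self):
        t = np.linspace(0, 1, 10)
        with pytest.raises(ValueError):
            n_ca(t, np.ones_like(t), "up")

    def test_steady_state_efflux_matches_influx(self, control_metrics):
        m = control_metrics
        # conservation: at steady state, I_Ca entry ~ NCX + pump extrusion
        # (background Ca entry accounts for the small remainder)
        assert m.n_ca_naca + m.n_ca_pca == pytest.approx(m.n_ca_ica, rel=0.1)


class TestPercentChange:
    def test_identity_and_backcalculation(self):
        assert percent_change(5.0, 5.0) == 0.0
        # +45.6% applied to a 188.9 nM control lands at 275 nM
        assert percent_change(275.0, 188.9) == pytest.approx(45.58, abs=0.05)

    def test_antisymmetric_sign(self):
        assert percent_change(2.0, 1.0) > 0 > percent_change(1.0, 2.0)

    def test_zero_control_flagged(self):
        with pytest.raises(ZeroDivisionError):
            percent_change(1.0, 0.0)


class TestDyadDiffusionStats:
    def test_control_fraction_is_one(self, control_metrics):
        # no dyadic transporters: every Ca ion leaves the dyad by diffusion
        assert control_metrics.diffusion_fraction == pytest.approx(1.0, abs=1e-3)

    def test_metrics_resampling_invariance(self, params, settings):
        """Metrics computed on a 2x finer grid agree within interpolation
        tolerance."""
        from dyadca.engine import integrate_cycle
        prot = d.make_current_clamp(5.0, 600.0)
        y0 = d.assemble_state(params).y
        tr1 = integrate_cycle(params, d.CONTROL, d.NONE, prot, settings, y0,
                              dt=2e-4)
        tr2 = integrate_cycle(params, d.CONTROL, d.NONE, prot, settings, y0,
                              dt=1e-4)
        f1, _ = d.dyad_diffusion_stats(tr1)
        f2, _ = d.dyad_diffusion_stats(tr2)
        assert f1 == pytest.approx(f2, rel=0.02)

    def test_peaks_not_below_end_diastolic(self, control_metrics):
        m = control_metrics
        assert m.ca_dt_peak >= m.ca_dt_end
        assert m.ca_c_peak >= m.ca_c_end
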