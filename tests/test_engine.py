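"""Integration engine: determinism, conservation audits, pacing, traces."""

import numpy as np
import pytest

import dyadca as d
from dyadca.engine import SolverSettings, integrate_cycle, pace_to_steady_state
from dyadca.constants import FARADAY
from dyadca.protocols import ClampProtocol


def _one_beat(params, settings, dist=d.CONTROL, buffer=d.NONE, dt=None):
    prot = d.make_current_clamp(5.0, 600.0)
    y0 = d.assemble_state(params).y
    return integrate_cycle(params, dist, buffer, prot, settings, y0, dt=dt)


class TestDeterminism:
    def test_identical_inputs_identical_traces(self, params, settings):
        tr1 = _one_beat(params, settings)
        tr2 = _one_beat(params, settings)
        assert np.array_equal(tr1.states, tr2.states)
        assert tr1.meta["params_sha256"] == tr2.meta["params_sha256"]

    def test_zero_buffer_run_identical_to_control(self, params, settings):
        """A disabled buffer (zero pipette concentration) changes nothing."""
        tr_none = _one_beat(params, settings, buffer=d.NONE)
        tr_zero = _one_beat(params, settings, buffer=d.make_buffer("egta", 0.0))
        assert np.array_equal(tr_none.states, tr_zero.states)


class TestConservation:
    def test_closed_subsystem_mole_conservation(self, params, settings):
        """With all sarcolemmal Ca pathways disabled and no pipette, total
        cell Ca is constant to within 10x the solver's relative tolerance
        over 10 s."""
        prot = ClampProtocol(
            mode="current", freq=0.1, duration=10.0, stim_amplitude=1e-30,
            current_disables=("ca", "naca", "pca", "cab"))
        y0 = d.assemble_state(params)
        total0 = d.total_cell_calcium(y0, params)
        from dyadca.engine import _integrate_segment, _Ctx
        ctx = _Ctx(params, d.CONTROL, d.NONE, prot)
        _, ys = _integrate_segment(ctx, y0.y, 0.0, 10.0, 0.0, None,
                                   settings, dt=0.5)
        drift = [abs(d.total_cell_calcium(d.StateVector(y), params) - total0)
                 / total0 for y in ys]
        assert max(drift) < 10 * settings.rtol

    def test_global_calcium_audit_one_beat(self, params, settings):
        """Change in total cell Ca over a beat equals the integrated net
        transmembrane Ca flux (audit within 1e-3 relative)."""
        tr = _one_beat(params, settings, dt=2.0e-5)
        cur = tr.currents()
        total_start = d.total_cell_calcium(d.StateVector(tr.states[0]), params)
        total_end = d.total_cell_calcium(d.StateVector(tr.states[-1]), params)
        # net inward Ca mole flux, fmol: divalent currents + NCX (1 Ca per
        # elementary charge, inward current = influx... NCX extrudes on
        # inward current so sign flips)
        i_div = (cur["i_ca"] + cur["i_cab"] + cur["i_pca"]).to_numpy()
        i_ncx = cur["i_naca"].to_numpy()
        influx = (-np.trapezoid(i_div, tr.time) / (2 * FARADAY)
                  + np.trapezoid(i_ncx, tr.time) / FARADAY) * 1e-3 * 1e12
        scale = max(abs(total_start), abs(influx), 1e-12)
        assert abs((total_end - total_start) - influx) / scale < 1e-3

    def test_steady_state_flux_balance(self, control_5hz):
        """Over the steady-state cycle, net transmembrane Ca flux is < 1%
        of the influx."""
        cyc = control_5hz.cycle
        cur = cyc.currents()
        t = cyc.time
        ica_in = -np.trapezoid(cur["i_ca"].to_numpy(), t) / (2 * FARADAY)
        icab_in = -np.trapezoid(cur["i_cab"].to_numpy(), t) / (2 * FARADAY)
        ipca_out = np.trapezoid(cur["i_pca"].to_numpy(), t) / (2 * FARADAY)
        incx_out = -np.trapezoid(cur["i_naca"].to_numpy(), t) / FARADAY
        influx = ica_in + icab_in
        efflux = ipca_out + incx_out
        assert abs(influx - efflux) / influx < 0.01


class TestPacing:
    def test_already_periodic_converges_immediately(self, params, control_5hz):
        """Restarting from a steady-state end point converges in a few
        beats."""
        res = pace_to_steady_state(
            params, d.CONTROL, d.NONE, d.make_current_clamp(5.0, 600.0),
            SolverSettings(), criterion=1e-3,
            initial=control_5hz.cycle.final_state(), max_beats=30)
        assert res.converged
        assert res.n_beats <= 10

    def test_voltage_clamp_smoke(self, params, settings):
        """Reduced two-pulse voltage-clamp train: the command is followed,
        Cs-blocked K currents are exactly zero, I_Ca decays to the 0.37
        threshold, and the t-tubular dyadic transient exceeds the surface
        one (smaller t-tubular subsarcolemmal shell -> faster local rise
        and release activation)."""
        from dataclasses import replace
        from dyadca.engine import integrate
        from dyadca.metrics import t037
        prot = replace(d.make_voltage_clamp_train(), freq=0.5,
                       duration=4.0, n_pulses=2, analysis_pulse=2)
        tr = integrate(params, d.CONTROL, d.NONE, prot, settings)
        cur = tr.currents()
        assert np.all(cur["i_k1"].to_numpy() == 0.0)
        assert np.all(cur["i_kto"].to_numpy() == 0.0)
        sel = (tr.time >= prot.period) & (tr.time <= prot.period + 0.2)
        assert np.allclose(tr.v[sel][1:-1], 0.0)
        value, censored = t037(tr.time[sel], cur["i_ca"].to_numpy()[sel])
        assert not censored and 2.0 < value < 100.0
        assert tr.series("ca_dt")[sel].max() > tr.series("ca_ds")[sel].max()

    def test_convergence_metrics_recorded(self, control_5hz):
        h = control_5hz.history
        assert {"ca_c_end", "ca_nsr_end", "v_end", "apd50"} <= set(h.columns)
        assert len(h) == control_5hz.n_beats


class TestTrace:
    def test_time_grid_and_shapes(self, control_5hz):
        cyc = control_5hz.cycle
        assert np.all(np.diff(cyc.time) > 0)
        assert cyc.states.shape == (cyc.time.size, d.N_STATES)

    def test_metadata_sufficient_to_rerun(self, control_5hz):
        meta = control_5hz.cycle.meta
        assert "params_sha256" in meta and "protocol" in meta
        assert meta["solver"]["rtol"] == pytest.approx(1e-6)

    def test_csv_round_trip(self, tmp_path, params, settings):
        import pandas as pd
        tr = _one_beat(params, settings)
        path = tmp_path / "cycle.csv"
        tr.to_csv(path)
        header = path.read_text().splitlines()[0]
        assert header.startswith("# units: mV mA mM s mL")
        df = pd.read_csv(path, comment="#")
        np.testing.assert_allclose(df["ca_c"].to_numpy(), tr.series("ca_c"))

    def test_diffusion_flux_series_definition(self, params, settings):
        tr = _one_beat(params, settings)
        flux = tr.diffusion_flux_series("dt_st")
        v_dt = params.volume("dt")
        tau = params.get("tau_ca.dt_st")
        expected = v_dt * (tr.series("ca_dt") - tr.series("ca_st")) / tau * 1e9
        np.testing.assert_allclose(flux, expected)

    def test_convergence_study_tolerance_halving(self, params):
        """Halving tolerances changes the beat metrics far less than the
        acceptance band."""
        tight = SolverSettings(rtol=5e-7)
        base = SolverSettings()
        m1 = _one_beat(params, base)
        m2 = _one_beat(params, tight)
        p1 = m1.series("ca_dt").max()
        p2 = m2.series("ca_dt").max()
        assert abs(p1 - p2) / p2 < 0.01
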