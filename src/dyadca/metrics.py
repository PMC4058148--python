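"""Per-cycle summary metrics: n_Ca per pathway, peaks, end-diastolic levels,
APD50, T_0.37, dyadic diffusion statistics and percent changes vs control.

Conventions: end-diastolic ("_end") values are read at the last sample of
the cycle (just before the next stimulus); n_Ca is the time integral of the
Ca-carrying component of a pathway over one steady-state cycle, reported in
fmol/cycle with efflux positive for the removal pathways (NCX, sarcolemmal
Ca pump, SERCA) and influx positive for I_Ca; T_0.37 uses the literal 0.37
threshold (not 1/e); the dyadic diffusion fraction is cycle-integrated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import FARADAY, MMOL_PER_S_TO_FMOL_PER_S


class NoActionPotential(ValueError):
    """Raised when a trace contains no detectable action potential."""


@dataclass
class CycleMetrics:
    """Summary of one steady-state cycle (units: fmol/cycle, mM, ms)."""

    n_ca_naca: float
    n_ca_pca: float
    n_ca_up: float
    n_ca_ica: float
    ca_dt_peak: float
    ca_ds_peak: float
    ca_c_peak: float
    ca_dt_end: float
    ca_c_end: float
    ca_nsr_end: float
    apd50: float | None
    max_dyad_flux: float        # fM/s, t-tubular dyad -> subsarcolemmal
    diffusion_fraction: float


def _interp_crossing(t: np.ndarray, x: np.ndarray, level: float,
                     start: int = 0, direction: str = "down") -> float | None:
    """First linear-interpolated time where x crosses ``level`` after
    ``start``; ``direction`` selects downward or upward crossings."""
    for i in range(start, len(x) - 1):
        a, b = x[i], x[i + 1]
        hit = (a >= level >= b) if direction == "down" else (a <= level <= b)
        if hit and a != b:
            frac = (a - level) / (a - b)
            return float(t[i] + frac * (t[i + 1] - t[i]))
        if hit:
            return float(t[i])
    return None


def apd50(trace, v: np.ndarray | None = None) -> float:
    """Action-potential duration at 50% repolarization, ms.

    The AP is measured from the upstroke (max dV/dt) to the interpolated
    crossing of the 50% level between the AP peak and the pre-stimulus
    diastolic potential.  Raises :class:`NoActionPotential` on flat traces.
    """
    t = np.asarray(trace.time, float) if hasattr(trace, "time") else None
    if v is None:
        v = trace.v
    v = np.asarray(v, float)
    if t is None:
        raise ValueError("apd50 needs a trace with a time grid")
    v_dia = v[0]
    peak_idx = int(np.argmax(v))
    v_peak = v[peak_idx]
    if v_peak - v_dia < 30.0:  # mV; no regenerative upstroke
        raise NoActionPotential("no action potential detected")
    dvdt = np.gradient(v, t)
    # first sample of the fast upstroke (argmax alone is unstable on ramps
    # where the slope is constant to rounding)
    upstroke_idx = int(np.argmax(dvdt >= 0.9 * dvdt.max()))
    t_up = t[upstroke_idx]
    level = v_dia + 0.5 * (v_peak - v_dia)
    t_cross = _interp_crossing(t, v, level, start=peak_idx, direction="down")
    if t_cross is None:
        raise NoActionPotential("no 50% repolarization within the cycle")
    return (t_cross - t_up) * 1.0e3


def t037(time: np.ndarray, ica: np.ndarray) -> tuple[float, bool]:
    """Time for I_Ca to decay to 0.37 of its peak amplitude, ms.

    ``ica`` is the (negative, inward) L-type current during a voltage step.
    Returns ``(value_ms, censored)``; when the current never reaches the
    threshold within the trace, the pulse duration is returned with
    ``censored=True``.
    """
    t = np.asarray(time, float)
    i = np.asarray(ica, float)
    mag = -i  # inward current -> positive magnitude
    peak_idx = int(np.argmax(mag))
    peak = mag[peak_idx]
    if peak <= 0:
        raise ValueError("no inward current in trace")
    level = 0.37 * peak
    t_cross = _interp_crossing(t, mag, level, start=peak_idx, direction="down")
    if t_cross is None:
        return (t[-1] - t[peak_idx]) * 1.0e3, True
    return (t_cross - t[peak_idx]) * 1.0e3, False


def n_ca(time: np.ndarray, flux: np.ndarray, kind: str,
         params=None) -> float:
    """Cycle-integrated Ca moved by one pathway, fmol/cycle.

    ``kind`` selects the conversion: ``"naca"`` (1 Ca per elementary
    charge), ``"ca"`` or ``"pca"`` or ``"cab"`` (divalent current), or
    ``"up"`` (flux already in mM/s referred to the cytosolic volume; needs
    ``params``).  Sign convention: positive = Ca extrusion for the removal
    pathways, positive = Ca entry for I_Ca.
    """
    t = np.asarray(time, float)
    x = np.asarray(flux, float)
    if t.ndim != 1 or t.size != x.size:
        raise ValueError("time/flux length mismatch")
    integral = float(np.trapezoid(x, t))
    # currents are in mA: 1 mA*s = 1e-3 C
    if kind == "naca":
        mmol = -integral * 1.0e-3 / FARADAY          # efflux positive
    elif kind in ("ca",):
        mmol = -integral * 1.0e-3 / (2.0 * FARADAY)  # influx positive
    elif kind in ("pca", "cab"):
        mmol = integral * 1.0e-3 / (2.0 * FARADAY)   # efflux positive
    elif kind == "up":
        if params is None:
            raise ValueError("n_ca kind 'up' requires params")
        mmol = integral * params.volume("c") * 1.0e-3
    else:
        raise ValueError(f"unknown pathway kind {kind!r}")
    return mmol * 1.0e12  # -> fmol


def percent_change(metric_test: float, metric_control: float) -> float:
    """100 * (test - control) / control; raises on a zero control value."""
    if metric_control == 0:
        raise ZeroDivisionError("percent_change undefined for zero control")
    return 100.0 * (metric_test - metric_control) / metric_control


def dyad_diffusion_stats(trace, site: str = "t") -> tuple[float, float]:
    """(max dyad->subsarcolemmal Ca flux in fM/s, cycle diffusion fraction).

    The fraction is the cycle-integrated diffusive efflux from the dyad
    divided by the total cycle-integrated Ca leaving it (diffusion plus the
    dyadic SERCA, NCX and sarcolemmal-pump removal at that site), counting
    only outward-directed contributions.
    """
    link = "dt_st" if site == "t" else "ds_ss"
    flux = trace.diffusion_flux_series(link)  # fM/s, dyad -> subsarcolemmal
    t = trace.time
    max_flux = float(np.max(flux))
    diff_out = float(np.trapezoid(np.clip(flux, 0.0, None), t))  # fmol

    cur = trace.currents()
    vol_c = trace.params.volume("c")
    suffix = "dt" if site == "t" else "ds"
    up = cur[f"j_up_{suffix}"].to_numpy()  # mM/s, cytosol-referenced
    up_fmol = float(np.trapezoid(up, t)) * vol_c * 1.0e-3 * 1.0e12
    i_naca = cur[f"i_naca_{suffix}"].to_numpy()
    naca_fmol = float(np.trapezoid(np.clip(-i_naca, 0.0, None), t)) \
        * 1.0e-3 / FARADAY * 1.0e12
    i_pca = cur[f"i_pca_{suffix}"].to_numpy()
    pca_fmol = float(np.trapezoid(np.clip(i_pca, 0.0, None), t)) \
        * 1.0e-3 / (2.0 * FARADAY) * 1.0e12
    total_out = diff_out + up_fmol + naca_fmol + pca_fmol
    if total_out <= 0:
        raise ValueError("no Ca left the dyad over this cycle")
    return max_flux, diff_out / total_out


def cycle_metrics(trace) -> CycleMetrics:
    """All per-cycle summaries for a steady-state cycle trace."""
    t = trace.time
    cur = trace.currents()
    try:
        apd = apd50(trace)
    except NoActionPotential:
        apd = None
    max_flux, diff_frac = dyad_diffusion_stats(trace, "t")
    return CycleMetrics(
        n_ca_naca=n_ca(t, cur["i_naca"].to_numpy(), "naca"),
        n_ca_pca=n_ca(t, cur["i_pca"].to_numpy(), "pca"),
        n_ca_up=n_ca(t, cur["j_up"].to_numpy(), "up", trace.params),
        n_ca_ica=n_ca(t, cur["i_ca"].to_numpy(), "ca"),
        ca_dt_peak=float(np.max(trace.series("ca_dt"))),
        ca_ds_peak=float(np.max(trace.series("ca_ds"))),
        ca_c_peak=float(np.max(trace.series("ca_c"))),
        ca_dt_end=float(trace.series("ca_dt")[-1]),
        ca_c_end=float(trace.series("ca_c")[-1]),
        ca_nsr_end=float(trace.series("ca_nsr")[-1]),
        apd50=apd,
        max_dyad_flux=max_flux,
        diffusion_fraction=diff_frac,
    )
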