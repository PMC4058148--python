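"""Reduced analytic reference systems and toy traces for testing.

Everything here is deterministic and generated programmatically: reduced
two-compartment diffusion and single-buffer binding systems with closed-form
solutions (the oracles the diffusion and buffer kinetics are checked
against), and piecewise-analytic toy traces (triangular action potential,
exponential current decay, rectangular fluxes) whose metric values are known
by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp

from .params import ParameterError
from .topology import diffusion_flux
from .buffers import buffer_reaction_rate


@dataclass
class ReducedSystem:
    """A small ODE system with an evaluable closed-form reference."""

    kind: str
    y0: np.ndarray
    rhs: Callable[[float, np.ndarray], np.ndarray]
    closed_form: Callable[[np.ndarray], np.ndarray]  # t -> states (n_t, n_y)
    params: dict = field(default_factory=dict)

    def integrate(self, t_end: float, n: int = 201, rtol: float = 1e-10,
                  atol: float = 1e-12) -> tuple[np.ndarray, np.ndarray]:
        t = np.linspace(0.0, t_end, n)
        sol = solve_ivp(self.rhs, (0.0, t_end), self.y0, t_eval=t,
                        method="LSODA", rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(sol.message)
        return t, sol.y.T


def gen_two_compartment(v1: float, v2: float, tau: float,
                        c1_0: float, c2_0: float) -> ReducedSystem:
    """Closed two-compartment diffusion system.

    Convention matches the engine: tau relaxes compartment 1 toward 2 and
    the mirror term carries the volume ratio, so
    ``dc1 = -(c1-c2)/tau``, ``dc2 = +(v1/v2)(c1-c2)/tau``.
    The difference decays as exp(-t(1 + v1/v2)/tau) and both concentrations
    relax to the mole-weighted mean; total moles are conserved exactly.
    """
    if min(v1, v2, tau) <= 0:
        raise ParameterError("volumes and tau must be positive")
    rate = (1.0 + v1 / v2) / tau
    c_mean = (v1 * c1_0 + v2 * c2_0) / (v1 + v2)

    def rhs(t, y):
        g = diffusion_flux(y[0], y[1], tau)
        return np.array([-g, g * (v1 / v2)])

    def closed(t):
        t = np.asarray(t, float)
        d0 = c1_0 - c2_0
        d = d0 * np.exp(-rate * t)
        c1 = c_mean + d * v2 / (v1 + v2)
        c2 = c_mean - d * v1 / (v1 + v2)
        return np.stack([c1, c2], axis=-1)

    return ReducedSystem("two-compartment diffusion",
                         np.array([c1_0, c2_0]), rhs, closed,
                         {"v1": v1, "v2": v2, "tau": tau, "rate": rate,
                          "c_mean": c_mean})


def gen_buffer_relaxation(ca_fixed: float, b_total: float,
                          k_on: float, k_off: float) -> ReducedSystem:
    """Single buffer binding a clamped free Ca.

    Bound buffer relaxes mono-exponentially with rate k_on*ca + k_off toward
    the equilibrium b_total*ca/(ca + k_off/k_on).
    """
    if min(b_total, k_on) <= 0 or ca_fixed < 0 or k_off < 0:
        raise ParameterError("invalid buffer relaxation parameters")
    rate = k_on * ca_fixed + k_off
    b_eq = b_total * ca_fixed / (ca_fixed + k_off / k_on) if rate > 0 else 0.0

    def rhs(t, y):
        bound = y[0]
        return np.array([
            buffer_reaction_rate(ca_fixed, b_total - bound, bound, k_on, k_off)
        ])

    def closed(t):
        t = np.asarray(t, float)
        return (b_eq + (0.0 - b_eq) * np.exp(-rate * t))[..., None]

    return ReducedSystem("single-buffer binding", np.array([0.0]), rhs, closed,
                         {"rate": rate, "b_eq": b_eq})


# ---------------------------------------------------------------------------
# Toy traces with hand-computable metrics
# ---------------------------------------------------------------------------

@dataclass
class ToyTrace:
    """Analytic waveform sampled on a grid, with ground-truth metrics."""

    time: np.ndarray
    v: np.ndarray | None = None
    ica: np.ndarray | None = None
    flux: np.ndarray | None = None
    truth: dict = field(default_factory=dict)


def gen_triangular_ap(v_rest: float = -80.0, v_peak: float = 40.0,
                      t_upstroke: float = 1.0e-3, t_repol: float = 0.1,
                      dt: float = 2.0e-5, t_total: float = 0.2) -> ToyTrace:
    """Triangular action potential: linear upstroke then linear
    repolarization back to rest.  APD50 ground truth from geometry:
    the 50% level is reached halfway down the repolarization ramp."""
    t = np.arange(0.0, t_total + dt / 2, dt)
    v = np.full_like(t, v_rest)
    up = (t > 0) & (t <= t_upstroke)
    v[up] = v_rest + (v_peak - v_rest) * t[up] / t_upstroke
    rep = (t > t_upstroke) & (t <= t_upstroke + t_repol)
    v[rep] = v_peak - (v_peak - v_rest) * (t[rep] - t_upstroke) / t_repol
    apd50_truth = (t_upstroke + 0.5 * t_repol - 0.0) * 1e3  # ms, from upstroke at ~0
    return ToyTrace(time=t, v=v, truth={"apd50_ms": apd50_truth})


def gen_exponential_ica(tau: float = 0.02, peak: float = -1.0e-6,
                        dt: float = 1.0e-4, t_total: float = 0.2) -> ToyTrace:
    """Pure exponential inward-current decay; the literal 0.37 crossing is
    at -tau*ln(0.37) after the peak."""
    t = np.arange(0.0, t_total + dt / 2, dt)
    ica = peak * np.exp(-t / tau)
    t037_truth = -tau * np.log(0.37) * 1e3  # ms
    return ToyTrace(time=t, ica=ica, truth={"t037_ms": t037_truth})


def gen_rectangular_flux(amplitude: float = 1.0, width: float = 0.1,
                         dt: float = 1.0e-4, t_total: float = 0.5) -> ToyTrace:
    """Rectangular flux pulse; its integral is amplitude*width (the n_Ca
    ground truth in the flux's own amount units)."""
    t = np.arange(0.0, t_total + dt / 2, dt)
    flux = np.where(t <= width, amplitude, 0.0)
    return ToyTrace(time=t, flux=flux,
                    truth={"integral": amplitude * width})
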