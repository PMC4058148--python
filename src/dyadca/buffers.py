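"""Exogenous Ca2+ buffers (EGTA/BAPTA): mass-action binding, diffusion and
pipette dialysis.

Both chelators bind Ca by simple mass action; they differ ~100-fold in
on-rate (EGTA k_on = 5000 mM^-1 s^-1, BAPTA k_on = 500000 mM^-1 s^-1) at
similar affinity, which is what turns BAPTA into a fast Ca "shuttle" between
the dyadic and subsarcolemmal spaces and leaves EGTA a slow one.  Free and
Ca-bound buffer diffuse between every aqueous compartment pair that
exchanges Ca, and both species dialyse between pipette and cytosol.

Dissociation constants are not protocol inputs; the presets pin
K_d(EGTA) = 1.5e-4 mM and K_d(BAPTA) = 2e-4 mM (appropriate near pH 7.2),
with k_off = K_d * k_on.  Both are plain config values.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .params import ModelParameters, ParameterError


@dataclass(frozen=True)
class BufferSpec:
    """An exogenous chelator dialysed from the pipette."""

    name: str
    total_pipette_conc: float  # mM, total buffer in the pipette solution
    k_on: float                # mM^-1 s^-1
    k_off: float               # s^-1
    ca_pipette: float = 5.0e-7  # mM, free Ca in the pipette solution (0.5 nM)

    def __post_init__(self):
        if not self.k_on > 0:
            raise ParameterError("buffer k_on must be > 0")
        if self.k_off < 0:
            raise ParameterError("buffer k_off must be >= 0")
        if self.total_pipette_conc < 0:
            raise ParameterError("buffer concentration must be >= 0")

    @property
    def kd(self) -> float:
        return self.k_off / self.k_on

    @property
    def enabled(self) -> bool:
        return self.total_pipette_conc > 0

    def pipette_partition(self) -> tuple[float, float]:
        """(free, Ca-bound) buffer concentration in the pipette at its free
        Ca, mM."""
        bound = self.total_pipette_conc * self.ca_pipette / (self.ca_pipette + self.kd)
        return self.total_pipette_conc - bound, bound

    def with_conc(self, conc: float) -> "BufferSpec":
        return replace(self, total_pipette_conc=conc)


_EGTA_KD = 1.5e-4   # mM
_BAPTA_KD = 2.0e-4  # mM

NONE = BufferSpec("none", 0.0, k_on=5000.0, k_off=5000.0 * _EGTA_KD)


def egta(conc: float = 10.0, ca_pipette: float = 5.0e-7) -> BufferSpec:
    k_on = 5000.0
    return BufferSpec("EGTA", conc, k_on, k_on * _EGTA_KD, ca_pipette)


def bapta(conc: float = 10.0, ca_pipette: float = 5.0e-7) -> BufferSpec:
    k_on = 500000.0
    return BufferSpec("BAPTA", conc, k_on, k_on * _BAPTA_KD, ca_pipette)


def make_buffer(name: str, conc: float = 10.0, **kwargs) -> BufferSpec:
    name_l = name.lower()
    if name_l == "none" or conc == 0:
        return NONE
    if name_l == "egta":
        return egta(conc, **kwargs)
    if name_l == "bapta":
        return bapta(conc, **kwargs)
    raise ParameterError(f"unknown buffer preset {name!r}")


def buffer_reaction_rate(ca: float, b_free: float, b_bound: float,
                         k_on: float, k_off: float) -> float:
    """Rate of Ca-bound buffer formation, mM/s: k_on*ca*b_free - k_off*b_bound.

    The same quantity enters the free-Ca and free-buffer balances with the
    opposite sign.
    """
    if min(ca, b_free, b_bound) < -1e-12:
        raise ParameterError("buffer_reaction_rate: negative concentration")
    return k_on * ca * b_free - k_off * b_bound


def dialysis_flux(conc_intracellular: float, conc_pipette: float,
                  tau: float) -> float:
    """Rate of change of the intracellular concentration due to pipette
    exchange, mM/s (first order toward the pipette composition)."""
    if not tau > 0:
        raise ParameterError("dialysis_flux: tau must be > 0")
    return (conc_pipette - conc_intracellular) / tau


@dataclass
class ShuttleDiagnostics:
    """Dyad-minus-subsarcolemmal buffer concentration differences vs time.

    ``delta_bound``/``delta_free`` are per-membrane: index "t" uses the
    t-tubular pair (dt - st), "s" the surface pair (ds - ss).
    """

    time: np.ndarray
    delta_bound_t: np.ndarray
    delta_free_t: np.ndarray
    delta_bound_s: np.ndarray
    delta_free_s: np.ndarray


def shuttle_diagnostics(trace) -> ShuttleDiagnostics:
    """Compute the fast/slow shuttle gradients from a trace.

    Requires the exogenous-buffer species in the trace's state series.
    """
    needed = ("bext_ca_dt", "bext_ca_st", "bext_free_dt", "bext_free_st",
              "bext_ca_ds", "bext_ca_ss", "bext_free_ds", "bext_free_ss")
    missing = [n for n in needed if n not in trace.columns]
    if missing:
        raise KeyError(f"trace lacks buffer species: {', '.join(missing)}")
    s = trace.states
    return ShuttleDiagnostics(
        time=trace.time,
        delta_bound_t=s[:, trace.col("bext_ca_dt")] - s[:, trace.col("bext_ca_st")],
        delta_free_t=s[:, trace.col("bext_free_dt")] - s[:, trace.col("bext_free_st")],
        delta_bound_s=s[:, trace.col("bext_ca_ds")] - s[:, trace.col("bext_ca_ss")],
        delta_free_s=s[:, trace.col("bext_free_ds")] - s[:, trace.col("bext_free_ss")],
    )
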