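"""Compartment graph, state-vector layout and inter-compartment diffusion.

The cell is a set of well-mixed pools: bulk cytosol (``c``), surface and
t-tubular subsarcolemmal shells (``ss``, ``st``), surface and t-tubular
dyadic spaces (``ds``, ``dt``), network SR (``nsr``) and the two junctional
SR pools (``jsr_s``, ``jsr_t``), plus the t-tubular lumen on the
extracellular side and, in whole-cell configurations, a patch pipette.
Exchange between linked pools is first order: the concentration of the
referenced compartment relaxes toward its neighbour with a time constant
tau, and the mirror term is scaled by the volume ratio so that moles are
conserved exactly.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .params import ModelParameters, ParameterError


class Comp(str, enum.Enum):
    """Compartment labels."""

    C = "c"
    SS = "ss"
    ST = "st"
    DS = "ds"
    DT = "dt"
    NSR = "nsr"
    JSR_S = "jsr_s"
    JSR_T = "jsr_t"
    LUMEN = "lumen"
    EXTRACELLULAR = "e"
    PIPETTE = "p"


#: Intracellular aqueous compartments (carry free Ca and aqueous buffers).
AQUEOUS = (Comp.C, Comp.SS, Comp.ST, Comp.DS, Comp.DT)

#: All intracellular compartments counted in the cell Ca content audit.
INTRACELLULAR = AQUEOUS + (Comp.NSR, Comp.JSR_S, Comp.JSR_T)


@dataclass(frozen=True)
class Compartment:
    id: Comp
    volume: float  # mL

    def __post_init__(self):
        if not self.volume > 0:
            raise ParameterError(f"compartment {self.id.value}: volume must be > 0")


@dataclass(frozen=True)
class DiffusionLink:
    """First-order exchange link; ``tau`` relaxes ``source`` toward ``target``."""

    source: Comp
    target: Comp
    tau: float  # s
    species: str = "ca"  # "ca" | "buffer_free" | "buffer_bound"

    def __post_init__(self):
        if not self.tau > 0:
            raise ParameterError(
                f"link {self.source.value}->{self.target.value}: tau must be > 0")


def diffusion_flux(conc_source: float, conc_target: float, tau: float) -> float:
    """Rate of concentration change of the source pool, (c_s - c_t)/tau, mM/s.

    Antisymmetric in its first two arguments.  The caller applies this with a
    minus sign to the source and, scaled by the source/target volume ratio,
    with a plus sign to the target, which conserves moles.
    """
    if not tau > 0:
        raise ParameterError("diffusion_flux: tau must be > 0")
    return (conc_source - conc_target) / tau


# ---------------------------------------------------------------------------
# State vector layout
# ---------------------------------------------------------------------------

#: Canonical state ordering.  Fixed; all readers and writers use it.
STATE_NAMES: tuple[str, ...] = (
    "v",
    # gating
    "m", "h", "j",              # I_Na
    "d", "f", "fca_t", "fca_s",  # I_Ca (fca_* = Ca-dependent inactivation)
    "r_to", "s_to",             # I_Kto
    "r_ss",                     # I_Kss
    "y_f",                      # I_f
    "ryr_o_t", "ryr_a_t", "ryr_o_s", "ryr_a_s",  # RyR per junction
    # free Ca
    "ca_c", "ca_ss", "ca_st", "ca_ds", "ca_dt",
    "ca_nsr", "ca_jsr_s", "ca_jsr_t", "ca_lumen",
    # monovalent ions
    "na_i", "k_i",
    # endogenous buffer occupancies (Ca-bound concentration, mM)
    "b_cm_c", "b_cm_ss", "b_cm_st", "b_cm_ds", "b_cm_dt",
    "b_htrpn", "b_ltrpn",
    "b_cs_s", "b_cs_t",
    "b_ts",
    # exogenous buffer, free then Ca-bound, per aqueous compartment
    "bext_free_c", "bext_free_ss", "bext_free_st", "bext_free_ds", "bext_free_dt",
    "bext_ca_c", "bext_ca_ss", "bext_ca_st", "bext_ca_ds", "bext_ca_dt",
)

IDX: dict[str, int] = {name: i for i, name in enumerate(STATE_NAMES)}
N_STATES = len(STATE_NAMES)

_GATES = ("m", "h", "j", "d", "f", "fca_t", "fca_s", "r_to", "s_to", "r_ss",
          "y_f", "ryr_o_t", "ryr_a_t", "ryr_o_s", "ryr_a_s")
_CONCS = tuple(n for n in STATE_NAMES
               if n.startswith(("ca_", "b_", "bext_")) or n in ("na_i", "k_i"))


class StateValidationError(ValueError):
    def __init__(self, message: str, fields: list[str] | None = None):
        super().__init__(message)
        self.fields = fields or []


@dataclass
class StateVector:
    """Named view over the model state array (length ``N_STATES``)."""

    y: np.ndarray

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        if self.y.shape != (N_STATES,):
            raise StateValidationError(
                f"state vector must have length {N_STATES}, got {self.y.shape}")

    def __getattr__(self, name: str) -> float:
        idx = IDX.get(name)
        if idx is None:
            raise AttributeError(name)
        return float(self.y[idx])

    def __getitem__(self, name: str) -> float:
        return float(self.y[IDX[name]])

    def validate(self, params: ModelParameters | None = None) -> None:
        bad = [n for n in _CONCS if self.y[IDX[n]] < -1e-12]
        if params is not None:
            caps = {
                "b_cm_c": "cmdn", "b_cm_ss": "cmdn", "b_cm_st": "cmdn",
                "b_cm_ds": "cmdn", "b_cm_dt": "cmdn",
                "b_htrpn": "htrpn", "b_ltrpn": "ltrpn",
                "b_cs_s": "csqn", "b_cs_t": "csqn", "b_ts": "bts",
            }
            for name, buf in caps.items():
                total = float(params.get(f"buffers.{buf}.total"))
                if self.y[IDX[name]] > total * (1 + 1e-9):
                    bad.append(name)
        if bad:
            raise StateValidationError(
                f"invalid state entries: {', '.join(bad)}", bad)

    def to_series(self) -> pd.Series:
        return pd.Series(self.y, index=list(STATE_NAMES))

    @classmethod
    def from_series(cls, s: pd.Series) -> "StateVector":
        return cls(s.reindex(list(STATE_NAMES)).to_numpy())

    def copy(self) -> "StateVector":
        return StateVector(self.y.copy())


def _equilibrium_bound(ca: float, total: float, kon: float, koff: float) -> float:
    return total * ca / (ca + koff / kon)


def assemble_state(params: ModelParameters,
                   initial_conditions: Mapping[str, float] | None = None
                   ) -> StateVector:
    """Build a valid initial :class:`StateVector`.

    Concentrations default to the parameter file's ``initial`` block; gates
    default to their steady state at the resting potential; endogenous
    buffers default to equilibrium with the local free Ca; exogenous buffer
    entries default to zero.  ``initial_conditions`` overrides any state by
    name.
    """
    from .transport import gate_inf  # local import to avoid a cycle

    init = {str(k): float(v) for k, v in dict(params.get("initial")).items()}
    if initial_conditions:
        unknown = [k for k in initial_conditions if k not in IDX]
        if unknown:
            raise StateValidationError(
                f"unknown state names: {', '.join(sorted(unknown))}", unknown)

    y = np.zeros(N_STATES)
    v0 = float(init.get("v", -80.0))
    y[IDX["v"]] = v0
    for g in _GATES:
        y[IDX[g]] = gate_inf(g, v0, ca_local=float(init.get("ca_dt", 1e-4)),
                             params=params)
    for name in ("ca_c", "ca_ss", "ca_st", "ca_ds", "ca_dt", "ca_nsr",
                 "ca_jsr_s", "ca_jsr_t", "ca_lumen", "na_i", "k_i"):
        y[IDX[name]] = init[name.replace("ca_lumen", "ca_lumen")]
    # endogenous buffers at equilibrium with local Ca
    for comp in ("c", "ss", "st", "ds", "dt"):
        y[IDX[f"b_cm_{comp}"]] = _equilibrium_bound(
            y[IDX[f"ca_{comp}"]], float(params.get("buffers.cmdn.total")),
            float(params.get("buffers.cmdn.kon")), float(params.get("buffers.cmdn.koff")))
    for name, buf, ca_name in (("b_htrpn", "htrpn", "ca_c"),
                               ("b_ltrpn", "ltrpn", "ca_c"),
                               ("b_cs_s", "csqn", "ca_jsr_s"),
                               ("b_cs_t", "csqn", "ca_jsr_t"),
                               ("b_ts", "bts", "ca_lumen")):
        y[IDX[name]] = _equilibrium_bound(
            y[IDX[ca_name]], float(params.get(f"buffers.{buf}.total")),
            float(params.get(f"buffers.{buf}.kon")),
            float(params.get(f"buffers.{buf}.koff")))
    if initial_conditions:
        for k, v in initial_conditions.items():
            y[IDX[k]] = float(v)
    state = StateVector(y)
    state.validate(params)
    return state


def total_cell_calcium(state: StateVector, params: ModelParameters) -> float:
    """Total intracellular Ca content (free + buffer-bound), in fmol.

    Sums over the intracellular compartments only; the t-tubular lumen and
    pipette are extracellular-side pools.
    """
    mmol = 0.0
    for comp in AQUEOUS:
        c = comp.value
        conc = (state[f"ca_{c}"] + state[f"b_cm_{c}"] + state[f"bext_ca_{c}"])
        if comp is Comp.C:
            conc += state["b_htrpn"] + state["b_ltrpn"]
        mmol += params.volume(c) * conc * 1e-3
    mmol += params.volume("nsr") * state["ca_nsr"] * 1e-3
    mmol += params.volume("jsr_s") * (state["ca_jsr_s"] + state["b_cs_s"]) * 1e-3
    mmol += params.volume("jsr_t") * (state["ca_jsr_t"] + state["b_cs_t"]) * 1e-3
    return mmol * 1.0e12  # mmol -> fmol


def ca_links(params: ModelParameters) -> tuple[DiffusionLink, ...]:
    """The model's Ca diffusion links (pipette link added by the engine
    only in whole-cell configurations)."""
    t = params.get("tau_ca")
    return (
        DiffusionLink(Comp.DT, Comp.ST, float(t["dt_st"])),
        DiffusionLink(Comp.DS, Comp.SS, float(t["ds_ss"])),
        DiffusionLink(Comp.ST, Comp.C, float(t["st_c"])),
        DiffusionLink(Comp.SS, Comp.C, float(t["ss_c"])),
        DiffusionLink(Comp.JSR_T, Comp.NSR, float(t["jsr_t_nsr"])),
        DiffusionLink(Comp.JSR_S, Comp.NSR, float(t["jsr_s_nsr"])),
        DiffusionLink(Comp.LUMEN, Comp.EXTRACELLULAR, float(t["lum_e"])),
    )
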