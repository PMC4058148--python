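"""Sarcolemmal currents and SR fluxes.

Current inventory (per the compartmental cell diagram): fast Na current
I_Na, L-type Ca current I_Ca with voltage- and Ca-dependent inactivation,
transient outward and steady-state K currents I_Kto/I_Kss, inward rectifier
I_K1, hyperpolarization-activated I_f, background I_Kb/I_Nab/I_Cab, Na/Ca
exchange I_NaCa (3:1 stoichiometry), Na/K pump I_NaK and sarcolemmal Ca
pump I_pCa; SR fluxes are SERCA uptake J_up, RyR release J_rel per junction
and a passive NSR->cytosol leak.

Transporters are resolved per membrane site.  Sarcolemmal Ca transporters
occupy up to four sites (t-tubular/surface x dyadic/extradyadic) with
populations from :mod:`dyadca.distribution`; each site senses its local Ca
([Ca]_dt or [Ca]_ds at the dyads, [Ca]_st or [Ca]_ss extradyadically) and
faces the t-tubular lumen or the bath on the outside.  Ca-dependent
inactivation (CDI) of I_Ca is a per-membrane gate driven by the local
dyadic Ca of that membrane; its trajectory is the reported CDI_t / CDI_s
signal.

Gating kinetics use Boltzmann steady states with bell-shaped voltage
dependent time constants, parameterized for rat ventricle at room
temperature.  All constants live in the parameter file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import vt
from .distribution import DistributionFractions
from .params import ModelParameters, ParameterError

# ---------------------------------------------------------------------------
# Gating
# ---------------------------------------------------------------------------

#: Boltzmann midpoints/slopes for the voltage gates: inf = 1/(1+exp(-(v-vh)/k)).
_GATE_INF = {
    "m": (-45.0, 6.5),
    "h": (-76.0, -6.1),
    "j": (-76.0, -6.1),
    "d": (-13.0, 6.0),
    "f": (-23.0, -5.5),
    "r_to": (10.0, 11.0),
    "s_to": (-45.0, -6.9),
    "r_ss": (10.0, 11.0),
    "y_f": (-95.0, -8.0),
}

#: tau(v) = base + amp / cosh((v - vc)/kc), seconds.
_GATE_TAU = {
    "m": (2.0e-5, 3.5e-4, -45.0, 10.0),
    "h": (7.0e-4, 6.0e-3, -70.0, 12.0),
    "j": (5.0e-3, 4.0e-2, -70.0, 12.0),
    "d": (6.0e-4, 1.4e-3, -15.0, 12.0),
    "f": (2.5e-2, 1.0e-1, -30.0, 12.0),
    "r_to": (1.0e-3, 4.0e-3, 0.0, 25.0),
    "s_to": (2.0e-2, 2.7e-1, -45.0, 10.0),
    "r_ss": (5.0e-2, 3.5e-1, 0.0, 25.0),
    "y_f": (1.0, 1.0, -90.0, 20.0),
}


def _boltz(v: float, vh: float, k: float) -> float:
    return 1.0 / (1.0 + math.exp(-(v - vh) / k))


def gate_inf(name: str, v: float, ca_local: float,
             params: ModelParameters) -> float:
    """Steady-state value of a gate at potential ``v`` (mV) and local free
    Ca ``ca_local`` (mM; used by the Ca-sensing gates only)."""
    if name in ("fca_t", "fca_s"):
        km = float(params.get("currents.ca.km_fca"))
        return km / (km + ca_local)
    if name in ("ryr_o_t", "ryr_o_s"):
        km = float(params.get("ryr.km_o"))
        h = float(params.get("ryr.h_o"))
        r = (ca_local / km) ** h
        return r / (1.0 + r)
    if name in ("ryr_a_t", "ryr_a_s"):
        km = float(params.get("ryr.km_a"))
        h = float(params.get("ryr.h_a"))
        return 1.0 / (1.0 + (ca_local / km) ** h)
    vh, k = _GATE_INF[name]
    return _boltz(v, vh, k)


def gate_tau(name: str, v: float, params: ModelParameters) -> float:
    """Time constant of a gate at potential ``v``, seconds."""
    if name in ("fca_t", "fca_s"):
        return float(params.get("currents.ca.tau_fca"))
    if name in ("ryr_o_t", "ryr_o_s"):
        return float(params.get("ryr.tau_o"))
    if name in ("ryr_a_t", "ryr_a_s"):
        return float(params.get("ryr.tau_a"))
    base, amp, vc, kc = _GATE_TAU[name]
    return base + amp / math.cosh((v - vc) / kc)


# ---------------------------------------------------------------------------
# Current set
# ---------------------------------------------------------------------------

@dataclass
class CurrentSet:
    """All membrane currents (mA) and SR fluxes, resolved per site.

    Site suffixes: ``dt``/``ds`` t-tubular/surface dyad, ``st``/``ss``
    t-tubular/surface extradyadic (subsarcolemmal face).  SR fluxes J_up*
    are in mM/s referred to the cytosolic volume; J_rel* in mM/s referred to
    the JSR volume of that junction.
    """

    i_na_t: float = 0.0
    i_na_s: float = 0.0
    i_ca_dt: float = 0.0
    i_ca_ds: float = 0.0
    i_ca_st: float = 0.0
    i_ca_ss: float = 0.0
    i_kto: float = 0.0
    i_kss: float = 0.0
    i_k1: float = 0.0
    i_f: float = 0.0
    i_kb: float = 0.0
    i_nab: float = 0.0
    i_cab_st: float = 0.0
    i_cab_ss: float = 0.0
    i_naca_dt: float = 0.0
    i_naca_ds: float = 0.0
    i_naca_st: float = 0.0
    i_naca_ss: float = 0.0
    i_nak: float = 0.0
    i_pca_dt: float = 0.0
    i_pca_ds: float = 0.0
    i_pca_st: float = 0.0
    i_pca_ss: float = 0.0
    i_stim: float = 0.0
    j_up_c: float = 0.0
    j_up_dt: float = 0.0
    j_up_ds: float = 0.0
    j_leak: float = 0.0
    j_rel_t: float = 0.0
    j_rel_s: float = 0.0
    cdi_t: float = 1.0
    cdi_s: float = 1.0

    # whole-cell sums ------------------------------------------------------
    @property
    def i_na(self) -> float:
        return self.i_na_t + self.i_na_s

    @property
    def i_ca(self) -> float:
        return self.i_ca_dt + self.i_ca_ds + self.i_ca_st + self.i_ca_ss

    @property
    def i_naca(self) -> float:
        return (self.i_naca_dt + self.i_naca_ds
                + self.i_naca_st + self.i_naca_ss)

    @property
    def i_pca(self) -> float:
        return (self.i_pca_dt + self.i_pca_ds
                + self.i_pca_st + self.i_pca_ss)

    @property
    def i_cab(self) -> float:
        return self.i_cab_st + self.i_cab_ss

    @property
    def j_up(self) -> float:
        return self.j_up_c + self.j_up_dt + self.j_up_ds

    @property
    def i_membrane(self) -> float:
        """Sum of all ionic membrane currents (excludes the stimulus)."""
        return (self.i_na + self.i_ca + self.i_kto + self.i_kss + self.i_k1
                + self.i_f + self.i_kb + self.i_nab + self.i_cab
                + self.i_naca + self.i_nak + self.i_pca)


# ---------------------------------------------------------------------------
# Flux primitives
# ---------------------------------------------------------------------------

def serca_flux(ca_local: float, ca_nsr: float, density_fraction: float,
               params: ModelParameters) -> float:
    """SERCA flux at one site, mM/s referred to cytosolic volume.

    Reversible Hill pump: J = vmax * f * (fb - rb) / (1 + fb + rb) with
    fb = (ca_local/km)^h and rb = (ca_nsr/km_sr)^h, so net uptake vanishes
    when the cytosolic and luminal saturations balance (this is what pins
    the diastolic free Ca at a level set by the SR load).  Linear in the
    site's share of the pump population; monotone increasing in ca_local.
    """
    if not 0.0 <= density_fraction <= 1.0:
        raise ParameterError("serca density_fraction must lie in [0, 1]")
    if ca_local < 0 or ca_nsr < 0:
        raise ParameterError("serca_flux: negative concentration")
    vmax = float(params.get("serca.vmax"))
    km = float(params.get("serca.km"))
    km_sr = float(params.get("serca.km_sr"))
    hill = float(params.get("serca.hill"))
    fb = (ca_local / km) ** hill
    rb = (ca_nsr / km_sr) ** hill
    return vmax * density_fraction * (fb - rb) / (1.0 + fb + rb)


def cicr_release(ca_dyad: float, ca_jsr: float, trigger_state,
                 params: ModelParameters) -> float:
    """RyR release flux at one junction, mM/s referred to the JSR volume.

    ``trigger_state`` is the (activation, availability) gate pair of that
    junction.  The flux is gradient-driven and non-negative (the pore is
    treated as release-only; an empty JSR releases nothing).
    """
    o, a = trigger_state
    g = float(params.get("ryr.g"))
    return max(0.0, g * o * a * (ca_jsr - ca_dyad))


def _ghk_ca(v: float, ca_in: float, ca_out: float, vthermal: float) -> float:
    """GHK-shaped driving term for divalent Ca, dimensionless concentration
    units (mM); -> (ca_in - ca_out) as v -> 0."""
    x = 2.0 * v / vthermal
    if abs(x) < 1e-6:
        return ca_in - ca_out + 0.5 * x * (ca_in + ca_out) * 0.5
    ex = math.exp(x)
    return x * (ca_in * ex - ca_out) / (ex - 1.0)


# ---------------------------------------------------------------------------
# Full current computation
# ---------------------------------------------------------------------------

def compute_currents(state, v: float, params: ModelParameters,
                     dist: DistributionFractions,
                     ionic: dict | None = None,
                     disabled: frozenset[str] = frozenset(),
                     i_stim: float = 0.0,
                     sites: dict | None = None) -> CurrentSet:
    """Evaluate every membrane current and SR flux at one instant.

    ``state`` is a :class:`~dyadca.topology.StateVector` or a raw array in
    the canonical layout; ``v`` the membrane (or command) potential in mV;
    ``ionic`` optionally overrides bath concentrations (keys ``ca_e``,
    ``na_e``, ``k_e``); ``disabled`` is a set of current labels forced to
    exactly zero (e.g. the K currents under Cs-based voltage clamp).
    """
    from .topology import IDX, StateVector

    y = state.y if isinstance(state, StateVector) else state
    cur = params.data["currents"]
    vth = vt(params.temperature)

    if sites is None:
        sites = {tr: dist.sites(tr, params) for tr in ("ca", "naca", "pca")}

    ion = dict(params.data["ionic"])
    if ionic:
        ion.update(ionic)
    ca_e, na_e, k_e = float(ion["ca_e"]), float(ion["na_e"]), float(ion["k_e"])

    ca_c = y[IDX["ca_c"]]
    ca_ss = y[IDX["ca_ss"]]
    ca_st = y[IDX["ca_st"]]
    ca_ds = y[IDX["ca_ds"]]
    ca_dt = y[IDX["ca_dt"]]
    ca_nsr = y[IDX["ca_nsr"]]
    ca_lum = y[IDX["ca_lumen"]]
    na_i = max(y[IDX["na_i"]], 1e-6)
    k_i = max(y[IDX["k_i"]], 1e-6)

    e_na = vth * math.log(na_e / na_i)
    e_k = vth * math.log(k_e / k_i)

    out = CurrentSet()
    out.i_stim = i_stim
    out.cdi_t = y[IDX["fca_t"]]
    out.cdi_s = y[IDX["fca_s"]]

    # --- fast Na current
    if "na" not in disabled:
        g = float(cur["na"]["g"])
        frac_t = float(cur["na"]["frac_t"])
        i = g * y[IDX["m"]] ** 3 * y[IDX["h"]] * y[IDX["j"]] * (v - e_na)
        out.i_na_t, out.i_na_s = i * frac_t, i * (1.0 - frac_t)

    # --- L-type Ca current (GHK driving, per site, CDI per membrane)
    if "ca" not in disabled:
        p = float(cur["ca"]["p"])
        gate = y[IDX["d"]] * y[IDX["f"]]
        w_dt, w_ds, w_st, w_ss = sites["ca"]
        fca_t_, fca_s_ = y[IDX["fca_t"]], y[IDX["fca_s"]]
        out.i_ca_dt = p * w_dt * gate * fca_t_ * _ghk_ca(v, ca_dt, ca_lum, vth)
        out.i_ca_ds = p * w_ds * gate * fca_s_ * _ghk_ca(v, ca_ds, ca_e, vth)
        out.i_ca_st = p * w_st * gate * fca_t_ * _ghk_ca(v, ca_st, ca_lum, vth)
        out.i_ca_ss = p * w_ss * gate * fca_s_ * _ghk_ca(v, ca_ss, ca_e, vth)

    # --- K currents
    if "kto" not in disabled:
        out.i_kto = (float(cur["kto"]["g"]) * y[IDX["r_to"]] * y[IDX["s_to"]]
                     * (v - e_k))
    if "kss" not in disabled:
        out.i_kss = float(cur["kss"]["g"]) * y[IDX["r_ss"]] * (v - e_k)
    if "k1" not in disabled:
        rect = 1.0 / (1.0 + math.exp(0.07 * (v - e_k - 10.0)))
        kdep = k_e / (k_e + 0.21)
        out.i_k1 = float(cur["k1"]["g"]) * kdep * rect * (v - e_k)
    if "f" not in disabled:
        out.i_f = float(cur["f"]["g"]) * y[IDX["y_f"]] * (v + 20.0)
    if "kb" not in disabled:
        out.i_kb = float(cur["kb"]["g"]) * (v - e_k)

    # --- background Na and Ca
    if "nab" not in disabled:
        out.i_nab = float(cur["nab"]["g"]) * (v - e_na)
    if "cab" not in disabled:
        g = float(cur["cab"]["g"])
        frac_t = float(cur["cab"]["frac_t"])
        e_ca_t = 0.5 * vth * math.log(max(ca_lum, 1e-9) / max(ca_st, 1e-9))
        e_ca_s = 0.5 * vth * math.log(ca_e / max(ca_ss, 1e-9))
        out.i_cab_st = g * frac_t * (v - e_ca_t)
        out.i_cab_ss = g * (1.0 - frac_t) * (v - e_ca_s)

    # --- Na/Ca exchange, 3 Na : 1 Ca, per site with local Ca
    if "naca" not in disabled:
        k = float(cur["naca"]["k"])
        km_na = float(cur["naca"]["km_na"])
        km_ca = float(cur["naca"]["km_ca"])
        ksat = float(cur["naca"]["ksat"])
        eta = float(cur["naca"]["eta"])
        x = v / vth
        ef = math.exp(eta * x)
        er = math.exp((eta - 1.0) * x)

        def _naca(ca_loc: float, ca_out: float, w: float) -> float:
            if w == 0.0:
                return 0.0
            num = na_i ** 3 * ca_out * ef - na_e ** 3 * ca_loc * er
            den = (km_na ** 3 + na_e ** 3) * (km_ca + ca_out) * (1.0 + ksat * er)
            return k * w * num / den

        w_dt, w_ds, w_st, w_ss = sites["naca"]
        out.i_naca_dt = _naca(ca_dt, ca_lum, w_dt)
        out.i_naca_ds = _naca(ca_ds, ca_e, w_ds)
        out.i_naca_st = _naca(ca_st, ca_lum, w_st)
        out.i_naca_ss = _naca(ca_ss, ca_e, w_ss)

    # --- Na/K pump
    if "nak" not in disabled:
        imax = float(cur["nak"]["imax"])
        km_na_p = float(cur["nak"]["km_na"])
        km_k = float(cur["nak"]["km_k"])
        sigma = (math.exp(na_e / 67.3) - 1.0) / 7.0
        fv = 1.0 / (1.0 + 0.1245 * math.exp(-0.1 * v / vth)
                    + 0.0365 * sigma * math.exp(-v / vth))
        out.i_nak = (imax * fv * (k_e / (k_e + km_k))
                     * na_i ** 1.5 / (na_i ** 1.5 + km_na_p ** 1.5))

    # --- sarcolemmal Ca pump, per site with local Ca
    if "pca" not in disabled:
        imax = float(cur["pca"]["imax"])
        km = float(cur["pca"]["km"])
        w_dt, w_ds, w_st, w_ss = sites["pca"]
        out.i_pca_dt = imax * w_dt * ca_dt / (ca_dt + km)
        out.i_pca_ds = imax * w_ds * ca_ds / (ca_ds + km)
        out.i_pca_st = imax * w_st * ca_st / (ca_st + km)
        out.i_pca_ss = imax * w_ss * ca_ss / (ca_ss + km)

    # --- SR fluxes
    f_dt, f_ds, f_bulk = dist.serca_sites()
    out.j_up_c = serca_flux(ca_c, ca_nsr, f_bulk, params)
    out.j_up_dt = serca_flux(ca_dt, ca_nsr, f_dt, params)
    out.j_up_ds = serca_flux(ca_ds, ca_nsr, f_ds, params)
    out.j_leak = float(params.get("serca.k_leak")) * (ca_nsr - ca_c)
    out.j_rel_t = cicr_release(
        ca_dt, y[IDX["ca_jsr_t"]],
        (y[IDX["ryr_o_t"]], y[IDX["ryr_a_t"]]), params)
    out.j_rel_s = cicr_release(
        ca_ds, y[IDX["ca_jsr_s"]],
        (y[IDX["ryr_o_s"]], y[IDX["ryr_a_s"]]), params)
    return out
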