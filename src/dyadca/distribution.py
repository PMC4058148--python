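"""Partitioning of Ca2+ efflux pathways between dyadic and extradyadic sites.

Each sarcolemmal Ca transporter (NCX, sarcolemmal Ca pump) has a fixed
membrane split between t-tubular and surface membranes (frac_t, frac_s from
the base parameter file) and a dyadic fraction f_d that relocates part of
the population from the subsarcolemmal face to the dyadic face of the same
membrane.  SERCA instead splits three ways: a dyadic fraction f_up_d,
distributed 0.8/0.2 between t-tubular and surface dyads (the proportion of
dyads on each membrane), with the remainder in the bulk cytosol.
Splitting redistributes capacity and never creates it: the site fractions
always sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .params import ModelParameters, ParameterError

#: Proportion of dyads on the t-tubular vs surface membrane.
DYAD_WEIGHT_T = 0.8
DYAD_WEIGHT_S = 0.2

_TOL = 1e-9


def _check_frac(name: str, value: float) -> None:
    if not (0.0 - _TOL <= value <= 1.0 + _TOL):
        raise ParameterError(f"{name} must lie in [0, 1], got {value}")


def split_membrane_transporter(f_dyad: float, frac_t: float, frac_s: float
                               ) -> tuple[float, float, float, float]:
    """Four-site split of a sarcolemmal transporter population.

    Returns the fractions at (t-tubular dyad, surface dyad, t-tubular
    extradyadic, surface extradyadic):
    ``(f_dyad*frac_t, f_dyad*frac_s, (1-f_dyad)*frac_t, (1-f_dyad)*frac_s)``.
    The four outputs sum to one.
    """
    _check_frac("f_dyad", f_dyad)
    _check_frac("frac_t", frac_t)
    _check_frac("frac_s", frac_s)
    if abs(frac_t + frac_s - 1.0) > 1e-6:
        raise ParameterError(
            f"membrane fractions must sum to 1, got {frac_t + frac_s}")
    return (f_dyad * frac_t, f_dyad * frac_s,
            (1.0 - f_dyad) * frac_t, (1.0 - f_dyad) * frac_s)


def split_serca(f_up_d: float) -> tuple[float, float, float]:
    """Three-site SERCA split: (t-tubular dyad, surface dyad, bulk cytosol).

    The dyadic fraction is weighted 0.8/0.2 between t-tubular and surface
    dyads; the remainder pumps from bulk cytosol.  Sums to one.
    """
    _check_frac("f_up_d", f_up_d)
    return (DYAD_WEIGHT_T * f_up_d, DYAD_WEIGHT_S * f_up_d, 1.0 - f_up_d)


@dataclass(frozen=True)
class DistributionFractions:
    """Dyadic fractions of the Ca flux pathways plus derived site splits.

    In the canned experiments f_naca_d, f_pca_d and f_up_d range over
    {0, 0.1, 0.2, 0.3} (0 = control) and f_ca_d stays at 1.
    """

    f_naca_d: float = 0.0
    f_pca_d: float = 0.0
    f_up_d: float = 0.0
    f_ca_d: float = 1.0

    def __post_init__(self):
        for name in ("f_naca_d", "f_pca_d", "f_up_d", "f_ca_d"):
            _check_frac(name, getattr(self, name))

    def sites(self, transporter: str, params: ModelParameters
              ) -> tuple[float, float, float, float]:
        """Four-site fractions (dt, ds, st, ss) for a sarcolemmal transporter
        (``naca``, ``pca`` or ``ca``), using the membrane split from the
        parameter file."""
        f_d = {"naca": self.f_naca_d, "pca": self.f_pca_d,
               "ca": self.f_ca_d}[transporter]
        frac_t = float(params.get(f"currents.{transporter}.frac_t"))
        return split_membrane_transporter(f_d, frac_t, 1.0 - frac_t)

    def serca_sites(self) -> tuple[float, float, float]:
        """(t-dyad, s-dyad, bulk) SERCA fractions."""
        return split_serca(self.f_up_d)


CONTROL = DistributionFractions()
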