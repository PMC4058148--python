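"""Model parameter set: loading, validation and overrides.

The full parameterization of the cell model (compartment volumes, transporter
maxima, buffer kinetics, inter-compartment exchange time constants, current
formulation constants) lives in a single human-editable YAML file.  The
package ships one canonical "control" configuration; every key can be
overridden programmatically via :meth:`ModelParameters.replace` using dotted
paths, or by editing a copy of the file.

Unit basis (used throughout, stated in the file header): mV, mA, mM, s, mL.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources
from typing import Any, Iterator, Mapping

import yaml


class ParameterError(ValueError):
    """Raised when a parameter set is incomplete or inconsistent.

    Carries the list of offending dotted keys in :attr:`fields`.
    """

    def __init__(self, message: str, fields: list[str] | None = None):
        super().__init__(message)
        self.fields = fields or []


#: Compartments whose fractional volumes must sum to 1 (intracellular aqueous).
INTRACELLULAR_FRACS = ("c", "ss", "st", "ds", "dt", "nsr", "jsr_s", "jsr_t")

_REQUIRED_SCALARS = [
    "membrane.cm",
    "temperature",
    "volumes.v_i",
    "volumes.v_lumen",
    "ionic.ca_e",
    "ionic.na_e",
    "ionic.k_e",
    "serca.vmax",
    "serca.km",
    "serca.km_sr",
    "serca.hill",
    "serca.k_leak",
    "ryr.g",
    "ryr.km_o",
    "ryr.h_o",
    "ryr.tau_o",
    "ryr.km_a",
    "ryr.h_a",
    "ryr.tau_a",
    "stimulus.amplitude",
    "stimulus.width",
]

_REQUIRED_GROUPS = {
    "volumes.frac": INTRACELLULAR_FRACS,
    "tau_ca": ("dt_st", "ds_ss", "st_c", "ss_c", "jsr_t_nsr", "jsr_s_nsr",
               "lum_e", "c_p"),
    "tau_buf": ("dt_st", "ds_ss", "st_c", "ss_c", "c_p"),
    "currents": ("na", "ca", "naca", "pca", "nak", "k1", "kto", "kss", "f",
                 "kb", "nab", "cab"),
    "buffers": ("cmdn", "htrpn", "ltrpn", "csqn", "bts"),
}


def _get_dotted(d: Mapping[str, Any], path: str) -> Any:
    node: Any = d
    for part in path.split("."):
        if not isinstance(node, Mapping) or part not in node:
            raise KeyError(path)
        node = node[part]
    return node


def _set_dotted(d: dict, path: str, value: Any) -> None:
    parts = path.split(".")
    node = d
    for part in parts[:-1]:
        node = node.setdefault(part, {})
    node[parts[-1]] = value


def _walk(d: Mapping[str, Any], prefix: str = "") -> Iterator[tuple[str, Any]]:
    for k, v in d.items():
        path = f"{prefix}{k}"
        if isinstance(v, Mapping):
            yield from _walk(v, path + ".")
        else:
            yield path, v


@dataclass(frozen=True)
class ModelParameters:
    """Immutable view over the full model parameterization.

    Access values with :meth:`get` (dotted path) or the convenience
    properties.  Construct with :meth:`default`, :meth:`from_yaml` or
    :meth:`from_dict`; derive variants with :meth:`replace`.
    """

    data: dict = field(repr=False)

    # -- construction -----------------------------------------------------
    @classmethod
    def default(cls) -> "ModelParameters":
        """The shipped control configuration."""
        text = (resources.files("dyadca") / "data" / "control.yaml").read_text()
        return cls.from_dict(yaml.safe_load(text))

    @classmethod
    def from_yaml(cls, path) -> "ModelParameters":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "ModelParameters":
        p = cls(data=copy.deepcopy(dict(data)))
        p.validate()
        return p

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.data, fh, sort_keys=False)

    # -- access -----------------------------------------------------------
    def get(self, path: str) -> Any:
        try:
            return _get_dotted(self.data, path)
        except KeyError:
            raise ParameterError(f"missing parameter {path!r}", [path]) from None

    def replace(self, **dotted: Any) -> "ModelParameters":
        """New parameter set with dotted-path overrides applied.

        Dots in keyword names are written as ``__`` (e.g.
        ``tau_ca__dt_st=1e-4``); a plain dict can be passed via
        :meth:`replace_map`.
        """
        return self.replace_map({k.replace("__", "."): v for k, v in dotted.items()})

    def replace_map(self, overrides: Mapping[str, Any]) -> "ModelParameters":
        data = copy.deepcopy(self.data)
        for path, value in overrides.items():
            _set_dotted(data, path, value)
        return ModelParameters.from_dict(data)

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        missing: list[str] = []
        for path in _REQUIRED_SCALARS:
            try:
                _get_dotted(self.data, path)
            except KeyError:
                missing.append(path)
        for group, keys in _REQUIRED_GROUPS.items():
            for key in keys:
                try:
                    _get_dotted(self.data, f"{group}.{key}")
                except KeyError:
                    missing.append(f"{group}.{key}")
        if missing:
            raise ParameterError(
                f"parameter set incomplete: {', '.join(sorted(missing))}", missing)

        bad: list[str] = []
        for path, value in _walk(self.data):
            if path.startswith(("tau_ca.", "tau_buf.")) and not value > 0:
                bad.append(path)
            if path.startswith("volumes.") and isinstance(value, (int, float)) \
                    and not value > 0:
                bad.append(path)
        fracs = self.data["volumes"]["frac"]
        total = sum(float(fracs[k]) for k in INTRACELLULAR_FRACS)
        if abs(total - 1.0) > 1e-6:
            bad.append("volumes.frac (sum != 1)")
        if bad:
            raise ParameterError(
                f"invalid parameter values: {', '.join(sorted(bad))}", bad)

    # -- derived ----------------------------------------------------------
    @property
    def cm(self) -> float:
        return float(self.get("membrane.cm"))

    @property
    def temperature(self) -> float:
        return float(self.get("temperature"))

    def volume(self, comp: str) -> float:
        """Compartment volume in mL.

        ``comp`` is one of the intracellular labels, or ``lumen`` for the
        t-tubular lumen.
        """
        if comp == "lumen":
            return float(self.get("volumes.v_lumen"))
        return float(self.get("volumes.v_i")) * float(self.get(f"volumes.frac.{comp}"))
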