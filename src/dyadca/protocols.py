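"""Stimulation and clamp protocols with their ionic boundary conditions.

Two canned protocols: steady-state current-clamp pacing (1 ms stimulus
pulses at 1 or 5 Hz, physiological bath) and the whole-cell voltage-clamp
train used for I_Ca inactivation analysis (six 200 ms steps from -80 to
0 mV at 0.1 Hz, Cs-blocked K currents, near-zero Na/K on both sides of the
membrane, 1 mM bath Ca, 0.5 nM pipette free Ca, analysis on the 6th pulse).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

from .params import ParameterError

#: Current labels forced to zero when K currents are blocked with Cs.
K_CURRENTS = ("kto", "kss", "k1", "kb", "f")


@dataclass(frozen=True)
class ClampProtocol:
    """A stimulation protocol plus the ionic conditions it imposes.

    ``mode`` is ``"current"`` or ``"voltage"``.  For current clamp the
    stimulus is a square pulse of ``stim_amplitude`` mA and ``stim_width`` s
    at ``freq`` Hz.  For voltage clamp, ``n_pulses`` steps of
    ``pulse_duration`` s from ``holding`` to ``step`` mV at ``freq`` Hz;
    ``analysis_pulse`` marks the pulse whose I_Ca is analysed.
    """

    mode: str
    freq: float                      # Hz
    duration: float                  # s, total protocol time
    stim_amplitude: float = 0.0      # mA (current clamp)
    stim_width: float = 1.0e-3       # s
    n_pulses: int = 0                # voltage clamp
    pulse_duration: float = 0.2      # s
    holding: float = -80.0           # mV
    step: float = 0.0                # mV
    analysis_pulse: int = 0          # 1-based
    ionic_conditions: dict = field(default_factory=dict)   # bath overrides, mM
    pipette_conditions: dict = field(default_factory=dict)  # pipette, mM
    current_disables: tuple[str, ...] = ()
    dialysis: bool = False           # pipette <-> cytosol exchange active

    def __post_init__(self):
        if self.mode not in ("current", "voltage"):
            raise ParameterError(f"unknown protocol mode {self.mode!r}")
        if not self.freq > 0:
            raise ParameterError("protocol frequency must be > 0")
        if not self.duration > 0:
            raise ParameterError("protocol duration must be > 0")
        if self.mode == "voltage" and self.analysis_pulse > self.n_pulses:
            raise ParameterError("analysis pulse index exceeds pulse count")

    # -- derived ----------------------------------------------------------
    @property
    def period(self) -> float:
        return 1.0 / self.freq

    @property
    def n_beats(self) -> int:
        """Number of stimuli over the full duration (current clamp)."""
        return int(round(self.duration * self.freq))

    def stimulus_times(self) -> list[float]:
        n = self.n_beats if self.mode == "current" else self.n_pulses
        return [k * self.period for k in range(n)]

    def command_voltage(self, t: float) -> float:
        """Voltage-clamp command at time ``t`` (voltage mode only)."""
        t_in = t % self.period
        pulse_idx = int(t // self.period)
        if pulse_idx < self.n_pulses and t_in < self.pulse_duration:
            return self.step
        return self.holding

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ClampProtocol":
        d = json.loads(text)
        d["current_disables"] = tuple(d.get("current_disables", ()))
        return cls(**d)


def make_current_clamp(freq: float, total_time: float = 600.0,
                       stim_amplitude: float | None = None,
                       dialysis: bool = False) -> ClampProtocol:
    """Steady-state pacing protocol at ``freq`` Hz (1 ms current pulses).

    Default bath: 1.2 mM Ca, 140 mM Na, 5.4 mM K.  ``stim_amplitude``
    defaults to the configured value in the parameter file (resolved by the
    engine when left ``None``).  ``dialysis=True`` attaches the pipette
    (used for the exogenous-buffer experiments).
    """
    if not freq > 0:
        raise ParameterError("pacing frequency must be > 0")
    return ClampProtocol(
        mode="current",
        freq=freq,
        duration=total_time,
        stim_amplitude=0.0 if stim_amplitude is None else stim_amplitude,
        stim_width=1.0e-3,
        ionic_conditions={"ca_e": 1.2, "na_e": 140.0, "k_e": 5.4},
        pipette_conditions={"ca_p": 5.0e-7} if dialysis else {},
        dialysis=dialysis,
    )


def make_voltage_clamp_train() -> ClampProtocol:
    """Whole-cell voltage-clamp train for I_Ca inactivation analysis.

    Six 200 ms pulses from -80 to 0 mV at 0.1 Hz; K currents disabled
    (Cs block); bath 1 mM Ca with Na/K ~1000x below normal; pipette 0.5 nM
    free Ca with near-zero Na/K dialysing the cell interior.
    """
    return ClampProtocol(
        mode="voltage",
        freq=0.1,
        duration=60.0,
        n_pulses=6,
        pulse_duration=0.2,
        holding=-80.0,
        step=0.0,
        analysis_pulse=6,
        ionic_conditions={"ca_e": 1.0, "na_e": 0.135, "k_e": 0.005},
        pipette_conditions={"ca_p": 5.0e-7, "na_p": 0.01, "k_p": 0.14},
        current_disables=K_CURRENTS,
        dialysis=True,
    )
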