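"""Physical constants in the model's unit basis.

The whole package works in a single unit basis: mV for membrane potential,
mA for membrane currents, mM for concentrations, s for time and mL for
volumes.  Derived outputs (e.g. femtomole-per-second diffusion fluxes) are
converted at the reporting layer only.
"""

#: Faraday constant, C/mmol (96485 C/mol).
FARADAY = 96.4853

#: Gas constant, mJ/(mmol*K)  (8.314 J/(mol*K)).
GAS_CONSTANT = 8.3145

#: mmol/s -> fmol/s  (1 mmol = 1e12 fmol).
MMOL_PER_S_TO_FMOL_PER_S = 1.0e12

#: mM -> nM.
MM_TO_NM = 1.0e6

#: mM -> uM.
MM_TO_UM = 1.0e3


def vt(temperature: float) -> float:
    """Thermal voltage RT/F in mV at the given temperature (K)."""
    return GAS_CONSTANT * temperature / FARADAY
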