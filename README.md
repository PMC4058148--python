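# dyadca

Compartmental simulation of intracellular Ca²⁺ dynamics in the rat
ventricular myocyte, with explicit dyadic Ca²⁺ nanodomains.

Cardiac excitation–contraction coupling is controlled by two very different
Ca²⁺ pools: the bulk cytosol, and the tiny dyadic clefts between the
sarcolemma (mostly in the t-tubules) and the junctional sarcoplasmic
reticulum (SR), where L-type Ca²⁺ entry triggers Ca²⁺-induced Ca²⁺ release
(CICR) and drives Ca²⁺-dependent inactivation (CDI) of the L-type current.
`dyadca` is a deterministic stiff-ODE model built to ask two questions about
this architecture:

1. What happens to cellular Ca²⁺ cycling when the Ca²⁺ *efflux* pathways —
   Na⁺/Ca²⁺ exchange (NCX), the sarcolemmal Ca²⁺ ATPase, and SERCA — are
   partially relocated from their bulk/subsarcolemmal positions into the
   dyads, where they see ~1000-fold higher Ca²⁺ during the transient?
2. How do the exogenous chelators EGTA and BAPTA (equal affinity, ~100-fold
   different on-rate) differentially buffer dyadic vs cytosolic Ca²⁺ when
   dialysed into the cell from a patch pipette, and how does that feed back
   on CDI of the L-type current?

The package is aimed at cardiac electrophysiologists and modellers who want
a small, fully inspectable cell model in which transporter location, dyad
geometry and buffer kinetics are first-class, editable parameters.

## The model

The cell is a graph of well-mixed pools: cytosol `c`; surface and t-tubular
subsarcolemmal shells `ss`, `st`; surface and t-tubular dyadic spaces `ds`,
`dt` (nanodomains, ~10⁻⁵ of cell volume); network SR `nsr`; junctional SR
`jsr_s`, `jsr_t`; the t-tubular lumen (which can deplete of Ca²⁺); bath and
pipette. Exchange between linked pools is first order,

    d[Ca]_a/dt = -([Ca]_a - [Ca]_b) / τ_ab,

with the mirror term scaled by the volume ratio so moles are conserved.
Membrane currents (I_Na, I_Ca with voltage- and Ca-dependent inactivation,
I_Kto, I_Kss, I_K1, I_f, backgrounds, I_NaCa at 3:1, I_NaK, I_pCa) are
resolved per membrane site; each sarcolemmal Ca²⁺ transporter can be split
four ways,

    (f_d·w_t, f_d·w_s, (1-f_d)·w_t, (1-f_d)·w_s)

over (t-dyad, s-dyad, t-extradyadic, s-extradyadic), where `f_d` is its
dyadic fraction and `w_t/w_s` its t-tubular/surface membrane split. SERCA
splits three ways, `(0.8·f_up_d, 0.2·f_up_d, 1-f_up_d)`, following the
0.8/0.2 proportion of dyads on the two membranes. SERCA itself is a
reversible Hill pump, RyR release is a gradient-driven flux gated by local
dyadic Ca²⁺ (activation + slow availability), and EGTA/BAPTA obey mass
action (`k_on·[Ca][B_free] - k_off·[B·Ca]`) in every aqueous pool, with
free and bound species diffusing between pools and dialysing from the
pipette. Units throughout: mV, mA, mM, s, mL.

The full parameterization ships as an editable YAML file
(`src/dyadca/data/control.yaml`); the 47-state layout is documented in
`dyadca.topology.STATE_NAMES`. A numba-compiled right-hand side mirrors the
readable reference implementation (the test suite holds them to machine
precision agreement).

## Worked example

Pace the control cell to a periodic steady state at 5 Hz and summarise the
final cycle:

```
$ dyadca run-paced --freq 5 --max-beats 20 --criterion 1e-3
{
  "n_beats": ...,
  "stopping_rule": "converged",
  "n_ca_fmol": {
    "naca": 0.0776,
    "pca": 0.0299,
    "up": 0.1485,
    "ica": 0.1055
  },
  "ca_c_peak_nM": 253.6,
  "ca_c_end_nM": 156.8,
  "ca_dt_peak_uM": 355.1,
  "ca_dt_end_nM": 138.5,
  "ca_nsr_end_mM": 1.206,
  "apd50_ms": 16.2,
  "max_dyad_flux_fM_s": 11.97,
  "diffusion_fraction": 1.0
}
```

Reading this: per 5 Hz cycle the L-type current brings in ~0.11 fmol of
Ca²⁺, SERCA moves ~0.15 fmol into the SR (the largest removal flux, as
expected for rat), NCX extrudes ~0.08 fmol and the sarcolemmal pump ~0.03;
the cytosolic transient runs from ~157 nM end-diastolic to ~254 nM while
the t-tubular dyadic nanodomain spikes to ~355 µM; the peak diffusive
Ca²⁺ flux out of the t-tubular dyad is ~12 fM/s (femtomole/s), and with no
efflux pathway located in the dyad the diffusion fraction is 1 — every ion
leaves the dyad by diffusion. Redistribution experiments
(`--f-up-d 0.3` etc.) and buffer experiments (`--buffer bapta
--buffer-conc 10 --freq 1`) change exactly these numbers; `dyadca
run-vclamp --buffer egta --buffer-conc 5` reports T₀.₃₇ of I_Ca under the
whole-cell voltage-clamp train.

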