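# dyadca control parameter set.
# Unit basis: mV (potential), mA (currents), mM (concentrations), s (time),
# mL (volumes); membrane capacitance in F.
#
# Compartments: c cytosol; ss/st surface and t-tubular subsarcolemmal spaces;
# ds/dt surface and t-tubular dyadic spaces; nsr network SR; jsr_s/jsr_t
# junctional SR at surface/t-tubular dyads; lumen = t-tubular lumen
# (extracellular side); e = bath; p = pipette.
#
# This file is the package's own base configuration, calibrated against the
# control behaviour of the reference compartmental rat-myocyte model family
# (diastolic Ca levels, dyadic transient amplitudes, dyad-subsarcolemmal
# diffusion flux); every key may be overridden.

membrane:
  cm: 1.0e-10            # F, whole cell (~100 pF)
temperature: 298.0       # K

volumes:
  v_i: 1.6e-8            # mL, total intracellular aqueous volume
  v_lumen: 1.6e-10       # mL, t-tubular lumen
  frac:                  # fractions of v_i; must sum to 1
    c: 0.921988
    ss: 0.026            # 0.65 of the subsarcolemmal pair
    st: 0.014            # 0.35 of the subsarcolemmal pair
    ds: 2.4e-6           # 0.2 of the dyadic (nanodomain) pair
    dt: 9.6e-6           # 0.8 of the dyadic (nanodomain) pair
    nsr: 0.034
    jsr_s: 0.0008
    jsr_t: 0.0032

ionic:                   # default bath composition, mM
  ca_e: 1.2
  na_e: 140.0
  k_e: 5.4

# Inter-compartment exchange time constants, s.  Naming a_b: tau is the
# relaxation time of compartment a toward b; the reverse term is scaled by
# the volume ratio so moles are conserved.
tau_ca:
  dt_st: 4.0e-6
  ds_ss: 4.0e-6
  st_c: 2.4e-3
  ss_c: 2.4e-3
  jsr_t_nsr: 0.05
  jsr_s_nsr: 0.05
  lum_e: 0.02
  c_p: 8.0
tau_buf:                 # exogenous buffer species (free and Ca-bound)
  dt_st: 8.0e-6
  ds_ss: 8.0e-6
  st_c: 1.2e-2
  ss_c: 1.2e-2
  c_p: 300.0

# Sarcolemmal currents.  g / p / imax / k are whole-cell maxima; frac_t is
# the t-tubular fraction of the transporter population.
currents:
  na:   {g: 8.0e-7, frac_t: 0.57}
  ca:   {p: 3.4e-6, frac_t: 0.80, km_fca: 2.0e-2, tau_fca: 1.2e-2}
  naca: {k: 1.35e-5, km_na: 87.5, km_ca: 1.38, ksat: 0.1, eta: 0.35, frac_t: 0.78}
  pca:  {imax: 1.5e-7, km: 5.0e-3, frac_t: 0.78}
  nak:  {imax: 8.8e-8, km_na: 10.0, km_k: 1.5, frac_t: 0.56}
  k1:   {g: 4.0e-8, frac_t: 0.56}
  kto:  {g: 1.8e-7, frac_t: 0.56}
  kss:  {g: 2.0e-7, frac_t: 0.56}
  f:    {g: 1.0e-9, frac_t: 0.56}
  kb:   {g: 1.0e-9, frac_t: 0.56}
  nab:  {g: 5.0e-10, frac_t: 0.56}
  cab:  {g: 2.0e-11, frac_t: 0.56}

serca:
  vmax: 0.5              # mM/s, referred to cytosolic volume
  km: 1.5e-4             # mM, cytosolic half-activation
  km_sr: 1.2             # mM, luminal back-inhibition
  hill: 2.0
  k_leak: 3.0e-3         # 1/s, NSR -> cytosol passive leak

ryr:                     # Ca-induced Ca release, per junction
  g: 150.0               # 1/s, maximal release rate constant
  km_o: 5.0e-2           # mM, activation half-saturation (local dyadic Ca)
  h_o: 4.0
  tau_o: 2.0e-3          # s
  km_a: 2.0e-2           # mM, availability half-inhibition
  h_a: 4.0
  tau_a: 0.15            # s

buffers:                 # endogenous Ca buffers (mass action)
  cmdn:  {total: 0.05,  kon: 34000.0, koff: 81.0}    # calmodulin, all aqueous spaces
  htrpn: {total: 0.14,  kon: 20000.0, koff: 0.066}   # troponin high-affinity, cytosol
  ltrpn: {total: 0.07,  kon: 40000.0, koff: 40.0}    # troponin low-affinity, cytosol
  csqn:  {total: 15.0,  kon: 100.0,   koff: 65.0}    # calsequestrin, JSR
  bts:   {total: 0.5,   kon: 1000.0,  koff: 1000.0}  # t-tubular luminal buffer

stimulus:
  amplitude: -4.0e-6     # mA, 1 ms current-clamp pulse (inward negative)
  width: 1.0e-3          # s

initial:                 # end-diastolic state of the control model paced
                         # to steady state at 5 Hz (shortens re-equilibration)
  v: -80.5653
  ca_c: 1.58354e-4
  ca_ss: 1.79425e-4
  ca_st: 1.02709e-4
  ca_ds: 2.14695e-4
  ca_dt: 1.38114e-4
  ca_nsr: 1.21738
  ca_jsr_s: 0.877407
  ca_jsr_t: 0.853432
  ca_lumen: 1.20102
  na_i: 14.5283
  k_i: 135.439
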