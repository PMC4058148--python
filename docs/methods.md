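# Methods

## Model structure and assumptions

The cell is a compartmental (well-mixed pool) model; there is no spatial
diffusion within a compartment. The intracellular aqueous volume
(1.6×10⁻⁸ mL) splits into bulk cytosol (92.2%), surface and t-tubular
subsarcolemmal shells (2.6% and 1.4%; their ratio 0.65/0.35 reflects the
fraction of each membrane that is non-junctional), surface and t-tubular
dyadic spaces (2.4×10⁻⁶ and 9.6×10⁻⁶ — true nanodomains, see below),
network SR (3.4%) and two junctional SR pools (0.08%, 0.32%, in the 0.2/0.8
proportion of dyads on the two membranes). A t-tubular lumen pool
(1.6×10⁻¹⁰ mL) sits on the extracellular side and exchanges with the bath
with τ = 20 ms, so lumenal Ca²⁺ can deplete during large t-tubular fluxes.
The membrane is isopotential (single V_m, C_m = 100 pF).

Inter-compartment exchange is first order in the concentration difference;
each link's τ refers to the relaxation of the named (source) compartment
and the mirror term carries the volume ratio, which conserves moles
exactly. The state vector has 47 entries (potential, 15 gating variables,
9 free Ca²⁺ pools, Na⁺/K⁺, 10 endogenous-buffer occupancies, 10 exogenous
buffer species); its ordering is fixed in `dyadca.topology.STATE_NAMES`
and used by every reader and writer.

Currents: fast Na⁺; L-type Ca²⁺ with GHK-shaped driving force (t-tubular
channels face the lumen, surface channels the bath), Boltzmann activation
`d`, voltage inactivation `f`, and a per-membrane Ca-dependent inactivation
gate (CDI) driven by the local dyadic Ca²⁺ (steady state
K_m/(K_m+[Ca]_dyad), K_m = 20 µM, τ = 12 ms); transient-outward,
steady-state and inward-rectifier K⁺ currents sized for the short rat
action potential; hyperpolarization-activated and background currents;
NCX (3 Na⁺ : 1 Ca²⁺, Luo–Rudy-form voltage dependence, each site sensing
its local Ca²⁺ and its own extracellular face); Na⁺/K⁺ pump; and a
low-affinity sarcolemmal Ca²⁺ pump (K_m = 5 µM). All extradyadic L-type
channels share the per-membrane CDI gate (with the default f_Ca,d = 1 there
are no extradyadic channels).

SR: SERCA is a reversible Hill pump,
J = V_max f (fb − rb)/(1 + fb + rb) with fb = ([Ca]_site/K_m)^2,
rb = ([Ca]_NSR/K_msr)^2 (V_max = 0.5 mM/s cytosol-referenced,
K_m = 0.15 µM, K_msr = 1.2 mM). The luminal back-reaction is what pins the
diastolic free Ca²⁺ at K_m·[Ca]_NSR/K_msr, so the diastolic level rises
with SR load and pacing rate. A passive NSR→cytosol leak
(3×10⁻³ s⁻¹·Δ[Ca]) closes the pump–leak cycle. RyR release per junction is
J_rel = g·o·a·([Ca]_JSR − [Ca]_dyad), release-only, with a fast activation
gate (half-activation 50 µM dyadic Ca²⁺, Hill 4, τ = 2 ms) and a slow
availability gate (half-inhibition 20 µM, Hill 4, τ = 150 ms) that
terminates release and leaves the junction refractory. Calsequestrin
(15 mM, mass action) buffers the JSR; calmodulin, troponin (high/low
affinity) and a lumenal membrane buffer use standard mass-action kinetics.

Exogenous chelators: EGTA (k_on = 5000 mM⁻¹s⁻¹) and BAPTA
(k_on = 500 000 mM⁻¹s⁻¹) with dissociation constants pinned at 150 nM and
200 nM (appropriate near pH 7.2), k_off = K_d·k_on; only k_on is a
literature constant, so K_d is an explicit config key. Free and Ca-bound
species diffuse along the same graph as Ca²⁺ (dyad links τ = 8 µs, shell→
cytosol 12 ms, shared by both species unless overridden) and dialyse
between pipette and cytosol with τ = 300 s — slow, reflecting both the
size of the chelator molecules and the fact that the whole-cell
experiments last ~600 s, so the pipette never fully re-equilibrates the
cell's Ca²⁺ content within a run. Pipette free Ca²⁺ is 0.5 nM in all
whole-cell configurations. Endogenous buffers do not dialyse. When a
buffer experiment starts, the chelator is initialized washed-in at the
pipette's total concentration with occupancy equilibrated to the resting
cytosolic Ca²⁺.

## Why the dyads are nanodomains

Two observable constraints fix the dyadic geometry jointly and leave no
freedom at mesodomain scale (~0.1% of cell volume):

- 10 mM EGTA reduces the dyadic transient only weakly (~20%) while 10 mM
  BAPTA nearly abolishes it. The capture probability of a Ca²⁺ ion during
  one dyadic residence is ≈ k_on·[B]·τ_residence; for this to be ~0.2 for
  EGTA (k_on·[B] = 5×10⁴ s⁻¹) the residence time must be ~4 µs. BAPTA's
  100-fold faster binding then captures essentially everything — the
  "fast shuttle".
- The peak diffusive flux out of the t-tubular dyad during a 5 Hz beat is
  ~11 fM/s at a dyadic peak of a few hundred µM. With
  flux = V_dyad·Δ[Ca]/τ, τ = 4 µs and Δ[Ca] ≈ 0.3 mM give
  V_dt ≈ 1.5×10⁻¹³ mL.

Both are satisfied simultaneously only by the nanodomain geometry used
here (dyadic pair ≈ 1.2×10⁻⁵ of the intracellular volume, τ_dyad = 4 µs).
The dyad is then in quasi-equilibrium with its subsarcolemmal shell except
during flux spikes, which is also what makes dyadic transporter fractions
behave sensibly at diastole.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| `currents.ca.p` | 3.4×10⁻⁶ | mA/mM (lumped) | sets per-beat Ca²⁺ entry (~0.1 fmol) and the dyadic trigger |
| `currents.ca.km_fca`, `tau_fca` | 0.02 mM, 12 ms | | CDI strength/speed; controls I_Ca decay and its relief by BAPTA |
| `currents.naca.k` | 1.35×10⁻⁵ | mA | NCX scale; balances influx at ~160–200 nM diastole at 5 Hz |
| `serca.vmax/km/km_sr` | 0.5 mM/s, 0.15 µM, 1.2 mM | | uptake rate, cytosolic affinity, luminal pin of diastolic Ca²⁺ |
| `ryr.g/km_o/km_a/tau_a` | 150 s⁻¹, 50 µM, 20 µM, 150 ms | | CICR gain, trigger threshold, release termination/refractoriness |
| `tau_ca.dt_st`, `volumes.frac.dt` | 4 µs, 9.6×10⁻⁶ | | dyad geometry (see above) |
| `stimulus.amplitude` | −4 µA × 1 ms | | smallest round amplitude that reliably elicits a regenerative AP |

Every key in `control.yaml` is overridable via
`ModelParameters.replace_map`; distribution fractions are accepted on
[0, 1] generally, with the canned experiments using {0, 0.1, 0.2, 0.3}.

## Numerics

LSODA (SciPy) at rtol = 10⁻⁶ with per-state absolute tolerances scaled to
each variable's units (10⁻⁵ mV, 10⁻⁸ for gates, 10⁻⁹ mM for aqueous Ca²⁺
and buffer species, 10⁻⁷ mM for SR/lumen pools, 10⁻⁶ mM for Na⁺/K⁺).
Integration restarts at every stimulus or clamp edge so discontinuities
never cross a solver step; under voltage clamp the potential is held
algebraically at the command value per segment. Recorded cycles are
sampled at 0.2 ms (≥1 kHz everywhere, finer than any metric's feature
scale); pacing-phase beats are sampled at 1 ms. Currents and per-link
fluxes are recomputed from the stored states (the model is deterministic,
so this is exact on the sampling grid). A numba kernel accelerates the
right-hand side ~150×; the pure-Python reference path remains the source
of truth and the suite asserts bitwise-level agreement between the two.

Steady state is detected per beat: the relative change of end-diastolic
[Ca²⁺]_c, [Ca²⁺]_NSR and V_m must fall below the criterion (default 10⁻⁵;
the desk-scale experiments use 10⁻⁴). APD₅₀ is recorded per beat but
excluded from the stopping rule because its crossing interpolation on the
coarse pacing grid jitters at the ~10⁻³ relative level. Pacing is capped
at the protocol duration (600 s of cell life); the shipped experiments use
caps of 250 beats (5 Hz) and 120 beats (1 Hz), starting from the shipped
end-diastolic control state, which the convergence logs show is deep into
the asymptotic regime for every reported metric. Slow Na⁺ accumulation
continues past these caps at ~10⁻⁴ per beat; it is common to paired
control/intervention runs and cancels in the reported percent changes.
Monotone end-diastolic Ca²⁺ growth over ~50 beats raises a Ca²⁺-overload
warning and stops pacing (the overload threshold is deliberately
conservative; the criterion is the monotone trend, not a level).

Metric conventions: end-diastolic values are the last sample before the
next stimulus; T₀.₃₇ uses the literal 0.37 threshold (not 1/e) with linear
interpolation between samples; the dyadic diffusion fraction is
cycle-integrated (diffusive efflux over diffusive efflux plus dyadic
removal), since an instantaneous ratio is undefined whenever the
instantaneous diffusive flux reverses; n_Ca sign conventions are efflux-
positive for NCX, the sarcolemmal pump and SERCA, influx-positive for
I_Ca.

## The reduced systems and toy traces

`dyadca.fixtures` generates the analytic references the engine and the
metrics are tested against: a closed two-compartment diffusion system
(mono-exponential relaxation to the mole-weighted mean at rate
(1 + v₁/v₂)/τ), single-buffer binding at clamped Ca²⁺ (relaxation at
k_on·Ca + k_off), and piecewise-analytic waveforms (triangular AP,
exponential current decay, rectangular flux pulses) whose APD₅₀, T₀.₃₇ and
integrals are known by construction. These fixtures validate the flux
forms, the integrator and the metric extractors — they do not validate the
biology; what passing them shows is that the machinery computes the model
faithfully, not that the model matches a given cell.

## Calibration of the base configuration and known discrepancies

The base parameter set is this package's own. It was calibrated once
against reference values for the rat ventricular myocyte under these
protocols — control diastolic and peak Ca²⁺ levels at 5 Hz, the peak
dyad→subsarcolemmal diffusion flux (~11 fM/s), the ~300 µM dyadic
transient under voltage clamp, a short APD₅₀, and SERCA > NCX >
sarcolemmal pump removal shares — and then frozen; the intervention
responses (redistribution and buffer effects) are emergent, not fitted.

Reproduced well (within ~±15%): the control and SERCA-redistributed peak
dyadic diffusion fluxes and the diffusion fraction ~0.8 at f_up,d = 0.3;
the combined-redistribution end-diastolic cytosolic Ca²⁺ (~275 nM); the
BAPTA suppression of the dyadic transient (~86–89%) versus the much weaker
EGTA suppression; the EGTA/BAPTA shuttle-gradient ordering; the relative
SR-load increase under 10 mM BAPTA; and the T₀.₃₇ ordering
control < EGTA < BAPTA under voltage clamp.

Known discrepancies (all deterministic, all documented rather than
re-tuned): the percent increases of SERCA and NCX turnover under combined
redistribution over-respond ~3–4× — with re-derived pump kinetics, the
dyadic transporter fractions saturate harder at nanodomain Ca²⁺ than in
the reference kinetics; the 1 Hz whole-cell diastolic dyadic Ca²⁺ runs
~100 nM rather than ~30 nM, because this configuration's SR-load/diastole
coupling (the SERCA luminal pin) has a weaker frequency dependence, and
the EGTA/BAPTA end-of-cycle dyadic levels inherit that offset; the L-type
influx increase under 10 mM BAPTA overshoots ~2× for the same reason the
CDI gate is a re-derivation. These would move together if the upstream
kinetics were substituted key-for-key in `control.yaml`.

## Limitations

Deterministic gating only (no stochastic RyR openings, so no sparks or
wave phenomena); single per-membrane CDI gate shared by extradyadic
channels; contraction is not modelled; buffer diffusion within the SR is
not modelled; fluorescent-indicator signals are not simulated; the model
is a single average cell — no population variability.
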