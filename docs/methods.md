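# Methods

## The system being modelled

`asmbatch` simulates two-phase anaerobic/anoxic batch experiments on
activated sludge performing combined nitrogen and phosphorus removal.
Each experiment runs 2.5 h without any electron acceptor, followed by
5.0 h with nitrate (a KNO3 spike at the phase switch), in a 4.0 L
stirred reactor.  External organic carbon is dosed at the start of
either phase: acetate (the canonical substrate of enhanced biological
phosphorus removal) or fusel oil, a distillery byproduct consisting
mostly of higher alcohols with a COD strength of ~1.69 kgO2/mL stock.
Three of the seven preset experiments interpose a chemical step at the
phase switch: the supernatant is decanted and its orthophosphate
precipitated with ferric chloride before the anoxic phase begins, which
suppresses the phosphate-uptake metabolism of denitrifying
polyphosphate-accumulating organisms (DPAOs) and thereby isolates their
contribution to nitrate removal.

## Biokinetic model

The core is the ASM2d family of activated-sludge models: a Gujer matrix
of 23 processes over 17 components (soluble substrates, nutrients,
dissolved gases, particulate substrate/inert pools, three biomass
guilds, and the PAO storage polymers polyphosphate X_PP and PHA X_PHA).
Every process rate is a maximum rate constant times Monod saturation
and inhibition switches times the responsible biomass.

Fusel oil enters as an additional state variable S_A1, an "external
readily biodegradable substrate" distinct from the fermentation-product
pool S_A.  Its defining property is asymmetric availability: ordinary
heterotrophs can ferment S_A1 to acetate anaerobically (rate constant
`q_fe_A1`) and grow on it under anoxic/aerobic conditions (`mu_H_A1`),
but PAOs cannot store it anaerobically.  A storage pathway for S_A1
gated on electron-acceptor presence (`q_PHA_A1`) exists and is small in
both calibrated profiles.  Four processes implement the extension:
aerobic and anoxic heterotrophic growth on S_A1, anaerobic fermentation
of S_A1 to S_A, and the gated PAO storage.

### Conservation closure

Rows of the matrix are specified mechanistically (substrate, product,
biomass, storage-polymer coefficients) and closed on three conservation
laws: COD (electron balance, with oxygen weighted -1, nitrate-N -64/14
and dinitrogen-N -24/14, so denitrifying 1 gN accepts 40/14 = 2.857
gCOD), nitrogen (closed through ammonium using the i_N composition
factors), and phosphorus (closed through orthophosphate; polyphosphate
carries weight one, which makes the P release coupled to anaerobic PHA
storage, Y_PO4 gP per gCOD stored, fall out of the closure rather than
being typed in).  A standing check verifies all three residuals below
1e-8 for every row; it holds by construction for any valid yields and is
property-tested over randomized parameters.

### What the lumped states do not resolve

Nitrate and nitrite are lumped into one state (measured nitrite was
below 0.1 mgN/L in these experiments); nitrification is present in the
matrix but inert here because no phase is aerated.  Glycogen-
accumulating organisms are not modelled: acetate uptake ceased when
polyphosphate was depleted in the source sludge, so their activity was
negligible.  Temperature and pH are recorded but not dynamic model
inputs (the experiments were controlled at 20 degC, pH 7.0).

## Batch simulation

Doses, nitrate spikes and the precipitation step are instantaneous
state jumps (the physical additions took seconds against a 7.5 h run).
Fusel COD splits into a readily biodegradable fraction f_RB = 0.85 to
S_A1 and the remainder to slowly biodegradable X_S; the precipitation
event multiplies S_PO4 by (1 - efficiency), default efficiency 0.90.
When several events share the phase-switch timestamp, precipitation is
applied first (it acts on the anaerobic supernatant), then the fresh
dose and the spike.  Integration is piecewise LSODA between event
breakpoints (rtol 1e-7, atol 1e-8), sampled on a 5-min grid; event
times carry duplicate samples holding the pre- and post-event states.
Halving the tolerances moves the reported rates by far less than 0.1%.

Alongside the 17 states the integrator accumulates, per denitrifying
process, the nitrate it consumed (the inputs of the flux attribution),
and a provenance split of the acetate pool: cumulative S_A inputs from
doses and fusel fermentation (external) versus wastewater fermentation,
PHA lysis and the initial pool (endogenous).

### Initial state from measured mixed liquor

Measured COD, phosphate, nitrate(+nitrite) and MLSS map to the state
through a fractionation: VSS = 0.75 MLSS, biomass COD = 1.42 gCOD/gVSS,
PAOs 17% and ordinary heterotrophs 32% of the volatile solids (values
taken over from full-scale simulation of the source plant), autotrophs
3%, polyphosphate reserve 0.10 and PHA 0.01 of the PAO biomass.  The
calibrated soluble-COD split is 1.0% fermentable / 1.6% VFA / 97.4%
inert, and 0.4% of the non-biomass particulate COD is initially slowly
biodegradable.  The near-inert soluble pool is forced by the reference
experiment: its anaerobic phosphate profile is almost flat (release
rate 0.4 mgP/gVSS/h), and since anaerobic P release is
stoichiometrically coupled to VFA storage, a fermentable initial pool
of more than a few mg/L would over-predict it several-fold.  A side
effect is that simulated anaerobic COD-removal efficiencies in the
undosed and fusel-dosed non-acclimated experiments undershoot the
measured ~24-27% — the model carries no anaerobic maintenance sink, so
the only anaerobic COD sink is P-coupled storage.  All fractionation
parameters are per-experiment configurable.

## Rate estimators

The three summary rates are ordinary least-squares slopes of
concentration series, normalised by VSS (g/L):

* PRR (anaerobic phosphate release) and PUR (anoxic phosphate uptake):
  the maximum-magnitude 45-min sliding-window slope within the phase.
  Release and uptake are fastest right after dosing, and the reported
  laboratory values are maxima; a full-phase window would average the
  initial burst against the saturated tail.
* NUR (anoxic nitrate utilization): full-phase slope, truncated where
  nitrate falls below 1 mgN/L so that substrate-starved tails do not
  dilute the estimate.

A slope whose sign contradicts the phase expectation (phosphate rising
anoxically, say) is flagged but its magnitude still returned.  On
noiseless linear data the estimator equals the analytic slope exactly;
it is invariant to time-origin shifts and equivariant under rescaling
of the biomass normalisation.  Derived quantities follow the
conventional summary table: phase removal efficiencies, the anaerobic
release-per-COD ratio (P released up to its maximum over COD consumed
to that time), and the anoxic P-uptake-per-nitrate ratio, computed from
the net concentration changes over the anoxic phase.

## Attribution of nitrate use

Two independent estimators decompose total anoxic nitrate consumption.

**Flux attribution** integrates each denitrifying process's nitrate
sink over the anoxic phase.  Group split: DPAO = anoxic polyphosphate
storage + anoxic PAO growth on PHA; DOHO = anoxic heterotrophic growth
on S_F, S_A and S_A1.  Source split: external carbon = the S_A1-driven
flux plus the externally-derived share of the S_A-driven flux (using
the provenance buckets, since dosed acetate and fermentation products
share one pool); stored PHA = the DPAO processes; endogenous = the
rest (hydrolysis/lysis products and the initial wastewater COD).  The
summed sinks close the simulated nitrate balance to integrator
accuracy, and the shares are insensitive to the output grid (5-min vs
1-min grids agree within 0.5 pp).

**Differencing** mirrors the experimental logic with counterfactual
runs: the full protocol (a); a no-dose reference (b), the in-silico
counterpart of the undosed reference experiment; anoxic PAO activity
disabled (c), by zeroing the PAO anoxic reduction factor with biomass
unchanged; and both (d).  External carbon = NUR(a) - NUR(b), PHA/DPAO =
NUR(a) - NUR(c), endogenous = NUR(d), normalised to one.  The no-dose
reference deliberately removes doses of *both* phases: defining it as
"everything the dosing added" reproduces the observed acclimated
external-carbon share (~60-65%), whereas stripping only the anoxic dose
misses carried-over substrate and understates it.

The two constructions answer slightly different questions — the
dose-effect reading charges PHA-mediated nitrate use to the dose that
loaded the PHA, the flux reading charges it to the PHA pool — so they
agree within ~15 pp per source on the non-acclimated experiments and
within 10 pp on the endogenous average, but diverge by up to ~24 pp on
the acclimated external-carbon share.  The differencing estimate is
used for the headline source split; a third, assumption-free estimator
for the DPAO group share is the precipitation pair: the relative NUR
drop between the acclimated experiments with and without phosphate
stripping, (NUR_without - NUR_with)/NUR_without.

## Calibration

The objective is SD-normalised least squares over the summary rates of
simulated scenarios against an observed-rates table (missing SDs
default to 10% of the value; the observed rates span 0.4-18.3, so
unweighted least squares would see only the largest releases).
Minimisation is Nelder-Mead with seeded multistarts — every evaluation
involves ODE solves, and the Monod switches make the surface
non-smooth — with bound clipping and bound-hit flags.

The two bundled profiles encode the biomass history.  The storage-rate
constants are q_PHA = 2.7 and q_PP = 2.0 1/d for non-acclimated sludge
and q_PHA = 7 1/d after ~50 days of fusel conditioning.  Acclimation is
otherwise expressed in the fusel-turnover constants — fermentation
q_fe_A1 0.005 (na) vs 3.16 (a) 1/d and anoxic growth mu_H_A1 0.17 (na)
vs 1.49 (a) 1/d: non-acclimated biomass barely touches fusel
anaerobically (hence the flat release profiles), acclimated biomass
ferments its readily biodegradable fraction within the first hour
(hence release rates of ~18 mgP/gVSS/h).  The remaining constants
(decay rates, anoxic reduction factors, storage half-saturations,
effective anoxic yields Y_H 0.62/0.53) were calibrated per profile
against the full observed surface; they sit within the ranges of the
ASM2d literature except where noted in the parameter files themselves.
Parameter-recovery runs close the loop: with 5% relative measurement
noise on synthetic tables, q_PHA is recovered with ~0-5% median error
over 10 seeds (noise-free recovery is exact to <2%).

### A note on one observed inconsistency

The observed acclimated fusel test reports NUR 3.7 mgN/gVSS/h, PUR
2.10 mgP/gVSS/h and an anoxic uptake stoichiometry of 1.11 mgP per mgN.
These three cannot hold together under any estimator windows: the NUR
implies ~43 mgN/L removed over the 5-h phase, the ratio then implies
~48 mgP/L taken up, but the anaerobic release peaks at ~39 mgP/L and
the PUR implies only ~25 mgP/L of uptake.  The calibration therefore
settles on a compromise — uptake nearly complete (ratio 0.90 mgP/mgN,
-19%), NUR 2.93 (-21%) and PUR 2.74 (+31%) — and the reproduction test
for the summary table is expected to flag exactly that pair.  Both
predicted-vs-observed regressions still explain >= 97% of the variance
in their families.

## Synthetic measurements

The raw concentration series of the study are not deposited, so a
generator stands in for them: simulated trajectories sampled on a
laboratory cadence (default 30 min) with zero-mean Gaussian noise at
the scale of the reported analytics (0.3 mg/L for phosphate and
nitrate, 3 mg/L for COD; a relative mode supports proportional noise),
truncated at zero.  Identical seeds give identical tables.  What the
generator deliberately does not emulate: sampling-volume losses,
autocorrelated drift of probes, filtration artefacts, and any
between-replicate variability of the biomass itself — so passing
recovery tests demonstrate estimator/calibration consistency, not
robustness to every failure mode of real batch data.  The recovery
harness samples at the simulator's own 5-min grid; coarser cadences add
a small systematic offset between the observed-side and predicted-side
estimators (about -5% at 15 min), which is a property of windowed slope
estimation on sparse grids, not of the noise.

## Numerical choices and degenerate inputs

Concentrations are clipped at zero inside the rate evaluation to guard
integrator overshoot; a state more negative than 1e-6 mg/L aborts with
a diagnostic instead of being silently clipped.  Ratio-type saturation
terms (X_PP/X_PAO, X_S/X_H) use a 1e-12 floor on the denominator, so
zero-biomass states are well-defined and static.  Undefined statistics
(zero observed variance, zero denominators in efficiencies and ratios)
raise; they are never coerced to numbers.  Rates are per day
internally; the user-facing time axis is hours.

## Known limitations

* One acetate pool: dosed acetate and fermentation products are
  chemically identical in the model; source attribution of that pool
  rests on the cumulative-input bookkeeping described above.
* No anaerobic maintenance: anaerobic COD removal is storage-coupled
  only (see the fractionation section).
* The fitted profiles are effective for 20 degC and this sludge; no
  temperature or pH corrections are applied.
* q_PHA is only weakly identified above ~7 1/d for the acclimated
  profile, where anaerobic release becomes fermentation-limited; the
  calibration reports bound hits rather than pretending a sharp
  optimum.
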