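# asmbatch

Model-based analysis of anaerobic/anoxic batch tests on activated
sludge performing combined nitrogen and phosphorus removal, with fusel
oil (a distillery byproduct of higher alcohols) and acetate as external
carbon sources.

Wastewater treatment plants removing N and P together depend on three
competing guilds: denitrifying "ordinary" heterotrophs (DOHOs),
polyphosphate-accumulating organisms (PAOs), and denitrifying PAOs
(DPAOs) that take up phosphate anoxically at the expense of nitrate and
stored PHA.  Dosing an external carbon source boosts denitrification,
but how the extra electrons split between these guilds — and between
the dose, stored polymers and endogenous substrate — cannot be measured
directly.  `asmbatch` answers that attribution question in silico for
two-phase batch experiments: 2.5 h anaerobic, then 5 h anoxic after a
KNO3 spike, with optional chemical phosphate precipitation between the
phases.

The package provides, for whoever needs to evaluate alternative carbon
sources for biological nutrient removal:

* an extended ASM2d biokinetic model (Gujer matrix with COD/N/P
  conservation closure) in which fusel oil enters as an "external
  readily biodegradable substrate" S_A1 — fermentable and oxidisable by
  heterotrophs, but not storable by PAOs without an electron acceptor;
* a batch simulator with dose/spike/precipitation events and
  per-process nitrate-sink accounting;
* the standard slope-based rate estimators: phosphate release rate
  (PRR), phosphate uptake rate (PUR), nitrate utilization rate (NUR),
  all in mg/gVSS/h, i.e. `rate = |slope(C_i, t_i)| / X_VSS`, plus
  removal efficiencies and stoichiometric ratios;
* two decompositions of total anoxic nitrate use, by microbial group
  (DPAO vs DOHO) and by carbon source (external / stored PHA /
  endogenous): process-flux integration and counterfactual
  differencing;
* calibration of storage-rate constants (q_PHA, q_PP, ...) against
  observed rate tables, and a synthetic-measurement generator with a
  parameter-recovery harness.

Two bundled parameter profiles represent sludge before and after ~50
days of acclimation to fusel oil (storage constants q_PHA = 2.7 vs
7 d^-1, and fast fusel fermentation after acclimation).

## Worked example

Simulate the acclimated fusel test (number 6: fusel dosed in both
phases, +48 mgN/L nitrate spike) and decompose its nitrate use:

```python
import asmbatch as ab

scenario = ab.preset_scenario(6)
kin, stoich = ab.load_profile(scenario.profile)   # "acclimated"
traj = ab.simulate_protocol(scenario.ic, scenario.protocol, kin, stoich)

rates = ab.trajectory_rates(traj)
print(f"PRR {rates['PRR']:.1f}  PUR {rates['PUR']:.1f}  "
      f"NUR {rates['NUR']:.1f} (mg/gVSS/h)")
print(f"peak anaerobic PO4 {rates['peak_anaerobic_PO4']:.1f} mgP/L, "
      f"anoxic uptake {rates['p_per_n']:.2f} mgP per mgN")

shares = ab.flux_attribution(traj)
print({k: round(v, 2) for k, v in shares.group_shares.items()})
```

prints

```
PRR 15.5  PUR 2.7  NUR 2.9 (mg/gVSS/h)
peak anaerobic PO4 40.0 mgP/L, anoxic uptake 0.90 mgP per mgN
{'DPAO': 0.19, 'DOHO': 0.81}
```

— the fermentable 85% of the fusel dose is stored as PHA within the
first hour, releasing phosphate to a 40 mgP/L peak; anoxically the
phosphate is taken back up at 0.9 mgP per mgN of nitrate denitrified,
with denitrifying PAOs carrying about a fifth of the nitrate flux and
ordinary heterotrophs the rest.

The same pipeline is scripted as a narrative analysis under
`analysis/` (`01_simulate_tests.py` ... `05_parameter_recovery.py`):
simulation of all seven tests, the summary-rate table with
observed-vs-predicted comparison, the attribution tables, the
storage-constant refit, and the noise-recovery check, all writing CSVs
under `results/`.

A thin CLI wraps the same functions:

```sh
asmbatch simulate --test 6 --out results
asmbatch decompose --test 6 --method both
asmbatch synth --test 3 --seed 42 --out meas.csv
asmbatch calibrate --free q_PHA --profile a --seed 1
asmbatch report
```

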