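# lymphpump

A multiscale sliding-filament model of lymphatic muscle pumping in a
single lymphangion.

Lymphatic muscle cells combine cardiac-like *phasic* and smooth-muscle-like
*tonic* contractile machinery.  `lymphpump` resolves both at the molecular
scale — a two-state (attach/detach) cross-bridge population for phasic
myosin and a four-state latch-model population for tonic myosin, each
evolved over a myosin-head displacement coordinate by a second-order
Godunov advection–reaction solver — couples them through a cell-scale
force network (series contractile elements with a strain-stiffening
parallel spring, a tonic parallel dashpot, and a Kelvin–Voigt cell
element), and embeds the cell in a lumped-parameter lymphangion with a
passive tube law, sigmoidal valve resistances, and pressure boundary
conditions.  Contractions are driven by a prescribed periodic intracellular
calcium transient through quasi-steady Hill saturations of troponin-C
(phasic attachment) and calmodulin (tonic phosphorylation).  The package
also computes the full energy ledger (ATP liberation, muscle work, viscous
and fluid losses, efficiencies) and ships one-at-a-time and Latin
hypercube / PRCC sensitivity machinery.

## Layout

| module | contents |
|---|---|
| `lymphpump.params` | all model constants, unit conventions, config loading/validation |
| `lymphpump.ecc` | calcium transient, Hill saturations, rate modulation |
| `lymphpump.crossbridge` | displacement-dependent rates, forces, energy-liberation integrands |
| `lymphpump.transport` | displacement grid, CFL control, Godunov stepper, moments |
| `lymphpump.cellmech` | row/cell force network, velocity partitioning, loss rates |
| `lymphpump.lymphangion` | tube law, valves, flows, diameter dynamics, wall-force balance |
| `lymphpump.simulate` | two-stage solve, periodicity detection, per-cycle metrics |
| `lymphpump.sensitivity` | OAT index, LHS designs, PRCC |
| `lymphpump.cli_io` | CLI, CSV/JSON artifact writers, plotting |

Internal units are CGS (cm, s, dyne, erg; calcium in µM).  Artifacts use
presentation units: µm, cmH2O, mL/hr, nL, dyne, erg.

## CLI

```sh
# single run to periodicity (writes timeseries.csv, metrics.json, params.json)
lymphpump run --config my.yaml --out runs/ref

# recalibrate the passive tube-law pressure scale to a target resting diameter
lymphpump calibrate --d0 200 --out tube_law.json

# pressure ladders and calcium-oscillation grids
lymphpump sweep --protocol afterload --pb 3.1:13:1 --out runs/afterload
lymphpump sweep --protocol calcium-osc --amplitudes 1,5,19 --frequencies 1,2,4 --out runs/osc

# sensitivity campaigns
lymphpump sensitivity --preset oat-rates --out runs/oat
lymphpump sensitivity --preset lhs --ranges ranges.json --trials 100 --out runs/lhs

# summary figure from a run directory
lymphpump plot runs/ref
```

Configuration is YAML with dotted or nested keys, e.g.

```yaml
vessel:
  p_a: 3.0        # cmH2O
  p_b: 3.1
  p_ext: 2.0
phasic:
  f1: 620.0       # 1/s
run:
  max_cycles: 20
```

Unknown keys are rejected; pressures are cmH2O and the calcium transient
levels (`calcium.Ca_amp`, `calcium.Ca_d`) are nM at the config surface.

## Notes on calibration

The passive tube law and valve parameters are not part of the published
parameter set; defaults here are calibrated so the passive (zero muscle
force) equilibrium at the reference pressures is 200 µm and the periodic
diastolic diameter is ≈165 µm.  `lymphpump calibrate` re-derives the
tube-law pressure scale for other targets.
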