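# nanoswitch

Simulation and quantification pipeline for tethered-particle switching
biosensors. A sensing surface carries thousands of microparticles, each
tethered by a short dsDNA linker; analyte molecules transiently sandwich a
particle to the substrate, switching it between a mobile (unbound) and a
tightly confined (bound) state. The package covers the whole chain from
single-particle x/y trajectories to concentration read-outs:

- **`nanoswitch.kinetics`** — stochastic simulator: continuous-time two-state
  Markov switching with a concentration-saturating binding rate, confined
  Brownian trajectories with localization noise, multiplicative sensor drift,
  and full injection schedules in fast Poisson *counts* mode or per-particle
  *trajectories* mode. Preset schedules (`figure3_series`, `figure4_milk`,
  `figure5_blind`) mirror the package's reference experiments.
- **`nanoswitch.readout`** — windowed diffusion-coefficient estimation,
  hysteresis bound/unbound state calling with a minimum-dwell filter, and
  counting of unbound-to-bound (UTB) transitions per 1-min interval.
- **`nanoswitch.calibration`** — drift-cancelling normalization against
  repeated zero/unity reference samples, four-parameter logistic
  dose-response fitting/inversion, and three quantification strategies
  (periodic refit / single fit / fixed curve).
- **`nanoswitch.metrics`** — CV of repeated 1-min concentration
  determinations, blank+3σ limit of detection, precision-profile limit of
  quantification, dilution correction, MARD vs a reference method, and
  normal/log-normal imprecision-distribution fits with Anderson–Darling
  goodness of fit.
- **`nanoswitch.cli` / `nanoswitch.io`** — `nanoswitch` command-line tool and
  plain-text table/YAML formats with provenance headers.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (parameter
recovery, drift recovery, oracle equivalence of the event counting,
simulator statistics, calibration algebra, precision-profile shape).

## CLI

```sh
# simulate a full concentration-series experiment (counts mode)
nanoswitch simulate --schedule figure3_series --seed 1 --mode counts --out out/

# per-particle trajectories + ground-truth event log
nanoswitch simulate --schedule figure4_milk --mode trajectories \
    --n-particles 50 --seed 1 --out out/

# trajectories -> UTB activity table
nanoswitch readout --trajectories out/trajectories.csv \
    --intervals out/intervals.csv --out out/activity.csv

# activity table -> concentrations + metrics (strategy 3 = fixed curve)
nanoswitch quantify --activity out/activity.csv --strategy 3 --out out/quant/

# seeded end-to-end example
nanoswitch demo --seed 1 --out out/demo/
```

Run configuration can also be given as YAML (`--config run.yaml`) with keys
`seed`, `params` (KineticParams fields), `readout`, `schedule` /
`schedule_name`, `strategy`, `fixed_curve`, `n_particles`, `mode`;
command-line flags override file values.

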