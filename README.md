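# capsidkinetics

Quantitative analysis pipeline for time-resolved small-angle scattering
(TR-SAXS/SANS) studies of template-directed self-assembly — e.g. viral
capsid subunits binding onto a genome or a synthetic polyelectrolyte.

The package implements:

- **`kinetics`** — the templated-assembly ladder `C_N + S <-> C_{N+1}`
  with uniform rate constants: a stiff ODE propagator (BDF, analytic
  Jacobian), an exact stochastic (Gillespie) simulator as an independent
  oracle, and the self-consistent equilibrium solution (truncated
  geometric occupancies; `K_inv = k_minus/k_plus` is the critical
  subunit concentration).
- **`scattering`** — forward intensities of subunit/complex mixtures, a
  *distribution-free upper bound* on the mean number of bound subunits
  per template computed from the forward intensity alone, iterative
  Guinier extraction of `(I0, R_g)`, form-factor traces at a probe
  wavenumber, and a templated-model intensity inversion.
- **`estimators`** — single/double exponential relaxation-time fits
  (multi-start, weighted), critical-concentration titration fits,
  binding free energy (explicit standard state), Smoluchowski
  diffusion-limited rates and apparent diffusion coefficients,
  Arrhenius activation-energy fits, and a full kinetic-model fit to
  `I0(t)` traces.
- **`synthetic`** / **`scenarios`** — TR frame-series generators with
  known ground truth (sphere / core-shell / Gaussian-chain form
  factors, D2O contrast matching, photon-limit noise) and three
  canonical scripted experiments (en-masse assembly, dilution-driven
  unbinding, pH-drop relaxation).
- **`pipeline`** / **`cli`** — workflow orchestration from curve series
  to fitted quantities and pathway classification
  (`en_masse` / `synchronous` / `indeterminate`).

Concentrations are molar; `q` is in 1/Å; lengths entering diffusion
formulas are meters.

## Command line

```sh
# generate a synthetic curve series (3-column .dat frames + manifest.csv
# + truth.json) for one of the canonical scenarios
capsidkinetics simulate --scenario en_masse --out runs/en_masse --seed 1

# analyze a series with a YAML experiment config (or --workflow/--data)
capsidkinetics analyze --config experiment.yaml --out report.json
capsidkinetics analyze --workflow dilution --data runs/dilution --out report.json

# fit a single trace CSV (time_s,value,sigma)
capsidkinetics fit --trace trace.csv --kind decay --phases 1 --out fit.json

# summarize a report
capsidkinetics report --report report.json

# run all three canonical scenarios end to end
capsidkinetics reproduce --out runs/repro --seed 1
```

A minimal `experiment.yaml`:

```yaml
workflow: assembly       # assembly | dilution | relaxation | titration | arrhenius
data_dir: runs/en_masse
c_S: 2.46e-05            # total subunit molarity
c_G: 1.64e-07            # total template molarity (or give rho + m_ratio)
db_G: 3.0                # excess scattering lengths (genome, subunit)
db_S: 1.0
q_probe: 0.044           # form-factor probe (1/A); q_band widens it
q_band: 0.2
```

Reports are deterministic JSON: extracted traces (`I0`, `R_g`, the
occupancy bound, `P(q_probe)`), all fit results with standard errors,
and derived quantities (binding/unbinding/structural times, critical
concentration, binding free energy, `k_plus`, apparent `D_S`,
activation energy) where the workflow provides them.

## File formats

- Curves: whitespace-delimited ASCII `q I sigma` with `#` headers
  (`.dat`); series as a directory plus `manifest.csv`
  (`filename,time_s`); ground truth as a JSON sidecar.
- Traces: CSV with `time_s,value,sigma` columns.
- Kinetic trajectories: CSV with `time_s, X_0..X_nmax, X_S, mean_N`.
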