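# dualres

Eco-evolutionary simulator for the joint evolution of **general** (continuous,
broad-spectrum) and **specific** (discrete, single-pathogen) host resistance
under endemic and foreign sterilizing pathogens with frequency-dependent
transmission.

The model is a deterministic SI compartment system: uninfected hosts carry a
general-resistance trait `q` (discretised on a 0–1 grid in steps of 0.01) and
either the susceptible `S` or resistant `R` allele at a specific-resistance
locus; two sterile infected pools track an endemic pathogen (transmission
`beta_e`, reduced by both forms of resistance) and a foreign pathogen
(`beta_f`, reduced by general resistance only). General resistance evolves by
adaptive dynamics: forward-Euler equilibration to `t = 1000`, then 5% of every
occupied trait bin moves to the adjacent bins, iterated up to 150 times, with
scheduled introductions of the `R` allele and the foreign pathogen. Closed-form
invasion analytics (`R0 = beta/mu`, invasion iff `beta_f (1-q) > mu`,
persistence iff `beta_f > (1-r) beta_e`) complement the simulations, and an
explicit two-locus, four-genotype model tests whether the evolved linkage
disequilibrium survives recombination.

## Library layout

| Module                  | Contents |
| ----------------------- | -------- |
| `dualres.model`         | trait grid, parameters, state, ODE right-hand sides (frequency- and density-dependent transmission) |
| `dualres.integrate`     | forward-Euler stepping and equilibration with end-of-phase clamping |
| `dualres.evolution`     | mutation kernel, adaptive-dynamics loop, stability test, outcome classification |
| `dualres.invasion`      | closed-form invasion/persistence thresholds |
| `dualres.recombination` | four-genotype two-locus model with a mating matrix at recombination rate `p` |
| `dualres.experiments`   | scenario presets (`fig1a` … `fig5_p05`), two-axis sweeps, CSV export |
| `dualres.cli`           | command-line interface |

## Command line

```sh
dualres run --scenario fig1b --out-dir out/         # single evolution trace CSV
dualres sweep --scenario fig2 --resolution 11 --out-dir out/
dualres recomb --scenario fig5_p005 --out-dir out/  # four-genotype trajectory CSV
dualres thresholds --q 0.41 --mu 0.2 --beta-f 0.6   # invasion analytics JSON
```

Custom runs take a YAML config (`params:`, `schedule:`, `integrator:`,
`sweep:` sections) via `--config`; flags override the file. Every command
writes a provenance JSON with the fully resolved parameter set — the pipeline
is deterministic, so that record is sufficient to reproduce any output
bit-identically.

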