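# thermofr

Temperature-dependent functional responses, metabolic scaling and
energetic efficiency for consumer–resource systems.

`thermofr` is an analysis pipeline for prey-depletion feeding trials,
respirometry and stream-survey data, built around three stages:

1. **Functional-response fitting by ODE simulation.** A predator in a
   closed arena depletes its prey, so the instantaneous response
   `F = aN/(1 + abN)` (attack rate `a = c·N^(h−1)`, handling time `b`)
   is integrated over the trial together with background mortality,

   `dN/dt = −cN^h/(1 + cbN^h) − mN`,

   and survivor counts enter a binomial likelihood on the ODE-predicted
   eaten fraction. Attack coefficient, handling time and mortality each
   carry Boltzmann–Arrhenius temperature dependence
   `r(T) = r0 · exp(E(T−T0)/(kTT0))`. Mortality is estimated first from
   predator-free controls and frozen into the depletion model. Across
   experimental settings, intercepts and activation energies may be
   shared or setting-specific; crossing response types I/II/III with
   the admissible sharing structures yields a 55-model zoo per
   predator, ranked by BIC. The Lambert-W random-predator closed form
   serves as an independent oracle for the solver.

2. **Metabolic scaling from respirometry.** O₂ consumption converts to
   J/h (0.4501 J/µmol) and is regressed on the log scale against body
   mass and the Arrhenius abscissa `x = (T−T0)/(kTT0)`, so temperature
   coefficients are activation energies in eV; candidate regressions
   (mass in/out, interaction, quadratic temperature) are BIC-ranked,
   and a negative quadratic yields a closed-form thermal optimum.

3. **Energetic efficiency.** Per stream, assimilated energy intake over
   metabolic expenditure: `y = ω(T) · F_E / I`, with `F_E` the energy
   feeding rate at the stream's prey density and `ω(T)` a
   logistic-Arrhenius assimilation efficiency. `y < 1` flags predators
   that cannot cover their metabolism by feeding.

A synthetic-data module generates feeding trials, respirometry records
and stream surveys with exactly the statistical structure the analysis
assumes, so every stage is testable end to end without external data.

## Worked example

Simulate the three-setting *Limnophora riparia* study design from its
published best-fitting parameters and refit the generating model
(type II, setting-specific attack intercepts `c0`, shared activation
energy `E_c`, shared handling time `b0`):

```python
import thermofr as tf
from thermofr.simulate import (limnophora_design, limnophora_truth,
                               simulate_fr_experiment, simulate_respirometry)

design, truth = limnophora_design(), limnophora_truth()
trials = simulate_fr_experiment(design, truth, seed=42)
mortality = tf.fit_mortality(trials[~trials["predator_present"]])

spec = tf.FRModelSpec("II", tf.ShareStructure("separate", "shared"),
                      tf.ShareStructure("shared", "zero"))
fit = tf.fit_fr_model(spec, trials, mortality, n_starts=5, seed=0)
print(fit.summary_frame()[["parameter", "dataset", "estimate", "se", "z"]]
      .round(3).to_string(index=False))
print(f"logLik = {fit.loglik:.2f}, k = {fit.k}, n = {fit.n_obs}, BIC = {fit.bic:.2f}")
```

```
parameter   dataset  estimate    se       z
       c0 field2015     1.774 0.226   2.536
       c0   lab2013     0.206 0.172  -9.160
       c0   lab2015     0.635 0.162  -2.796
      E_c  combined     0.510 0.136   3.755
       b0  combined     0.163 0.084 -21.477
logLik = -409.33, k = 5, n = 230, BIC = 845.85
```

One simulated replicate recovers the generating values (attack
intercepts 0.241/0.802/1.889 per day at 10 °C, shared `E_c = 0.704 eV`,
handling time 0.168 d) to within roughly one standard error each;
estimates are natural-scale, standard errors and z-values follow the
log-scale Wald convention for rate parameters (`z = ln(estimate)/SE`).
The respirometry stage works the same way:

```python
resp = simulate_respirometry(truth, seed=43, n_per_temp=[10, 9, 9, 9, 9])
winner = tf.fit_metabolic_models(resp)[0]
print(winner.summary_frame()[["term", "estimate", "se", "t"]].round(3).to_string(index=False))
print(f"r2 = {winner.r2:.2f}, BIC = {winner.bic:.2f}")
```

```
     term  estimate    se       t
intercept    -4.313 0.078 -55.302
        x     0.732 0.060  12.219
  ln_mass     0.697 0.093   7.535
r2 = 0.85, BIC = 54.84
```

BIC picks the mass-plus-temperature model; the `x` coefficient is the
respiration activation energy in eV (truth 0.687) and `ln_mass` the
allometric exponent (truth 0.525).

## Command line

```sh
thermofr simulate  --seed 1 --out data/ --predator limnophora
thermofr run-all   --seed 1 --trials data/trials.csv \
    --respirometry data/respirometry.csv --streams data/streams.csv \
    --out results/ --zoo-subset 10
```

Subcommands `simulate`, `fit-mortality`, `fit-fr`, `fit-metab`,
`energetics` and `run-all` write plain CSV/JSON artifacts, echo the run
configuration and stamp every table with its config hash. A YAML file
passed via `--config` overrides any default (solver tolerances,
optimizer starts, prey energetics, predator masses, field-rate
multiplier, area scaling).

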