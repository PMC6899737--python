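# Methods

This note documents the models implemented in `thermofr`, the numerical
and design choices behind them, and what the synthetic-data generators
do and do not emulate.

## The scientific problem

Two invertebrate predators (a muscid fly larva, *Limnophora riparia*,
and a cased caddisfly larva, *Potamophylax cingulatus*) feed on blackfly
larvae (Simuliidae) in a geothermally heated stream system spanning
roughly 4–25 °C. The package estimates how their feeding interactions
and metabolic demands scale with temperature, and combines the two into
a per-stream *energetic efficiency* — the ratio of assimilated energy
intake to metabolic expenditure — that can be screened against survey
abundances.

## Temperature scaling

Every biological rate is modelled as a Boltzmann–Arrhenius function of
absolute temperature,

    r(T) = r0 · exp(E (T − T0) / (k T T0)),

with `r0` the rate at the reference temperature `T0 = 283.15 K`,
activation energy `E` in eV and `k = 8.618 × 10⁻⁵ eV/K`. Temperatures
are Kelvin internally; all I/O is in °C and converted at the boundary.
`k` and the reference temperatures live in one injected
`PhysicalConstants` object because the assimilation-efficiency relation
uses its own reference `T0* = 293.15 K`: assimilation efficiency is the
logistic transform of Arrhenius-scaled odds,
`ω(T) = ω0 A / (1 + ω0 A)` with defaults `ω0 = e^2.266`,
`E_ω = 0.164 eV` (meta-analytic values for carnivorous invertebrates).
Over the 4–25 °C survey range this puts ω between about 0.87 and 0.92,
increasing with temperature.

## Prey depletion and the functional response

Feeding trials run 24 h without prey replacement, so the instantaneous
functional response `F = aN/(1 + abN)` (attack rate `a = c·N^(h−1)`,
handling time `b`, Hill exponent `h`) must be integrated over the
declining prey density together with background mortality:

    dN/dt = − c N^h / (1 + c b N^h) − m N.

Type I is encoded as `b = 0` with no extra feeding cut-off (a cut-off
would need a free parameter that a depletion design cannot identify);
`h` is fixed at 1 (types I/II) or 2 (type III), never estimated. The
batch of all arenas sharing a duration is integrated as one vector ODE
(adaptive RK45, rtol 1e−8, atol 1e−10, endpoint only) so a likelihood
evaluation costs a single solver call. The predator-free equation is
exactly exponential and is evaluated in closed form. The type II,
mortality-free case has the Lambert-W (random-predator) closed form,
kept as an independent oracle: ODE and closed form agree to ≤1e−6
relative across `a ∈ {0.1,1,5}`, `b ∈ {0,0.1,1}`, `N0 ∈ {1,…,60}`.

## Likelihood, sharing structures, BIC

Each arena contributes a binomial likelihood on the eaten count with
`p_eaten` the ODE-predicted eaten fraction (clipped at 1e−12) — the
standard likelihood for depletion designs with integer counts.
Estimation is two-stage: mortality parameters are first fitted to the
predator-free controls (candidates: `m0 = 0`; constant `m0`; Arrhenius
`m0, E_m`; BIC-selected) and frozen into the depletion equation before
the functional-response parameters are estimated.

Across experimental settings (e.g. two laboratory years and an in-situ
year) each parameter family (attack coefficient; handling time) can be
shared or setting-specific: shared intercept with zero or shared
activation energy, or separate intercepts with zero, shared or separate
activation energies — five admissible structures per family, because a
setting-specific activation energy only makes sense with
setting-specific intercepts. Types II and III cross both families
(5 × 5 each) and type I contributes its five attack structures, giving
the 55-model zoo per predator, independent of the number of settings.

Rate intercepts (`c0`, `b0`, `m0`) are fitted on the natural-log scale
(positivity; Wald z then equals `ln(estimate)/SE`, matching the
reported convention); activation energies are linear and unconstrained.
Optimisation is bounded L-BFGS-B from one central start plus seeded
random starts (intercepts log-uniform on [1e−3, 1e2], energies uniform
on [−1, 2]; 10 starts by default). Because the objective passes through
an adaptive ODE solver it carries ~rtol relative noise, so the
finite-difference gradient step is held at 1e−4 (well above the noise
floor) and the standard-error Hessian uses central differences with
relative step 5e−3. BIC is `k ln n − 2 logLik` with `n` the number of
arenas in the likelihood; ties break toward fewer parameters, then
enumeration order. Non-convergent fits are flagged and excluded from
selection.

## Metabolic scaling

Oxygen consumption (µmol O₂/h) converts to J/h via molar mass
(31.9988 g/mol), density (1.429 g/L) and 20.1 J/ml — 0.4501 J per µmol
O₂. Rates are regressed on the log scale against the Arrhenius abscissa
`x = (T − T0)/(k T T0)` — so temperature coefficients *are* activation
energies in eV — and log dry mass. Candidates cross temperature
(absent / linear / linear + quadratic), mass (in/out) and the
mass-by-temperature interaction; OLS, BIC-ranked. The quadratic is
applied on `x` (corroborated by the vertex of the published caddisfly
coefficients landing at ≈21.4 °C, matching the reported ≈21.5 °C
optimum). A negative quadratic coefficient gives an interior thermal
optimum at `x* = −E/(2q)`, mapped back through
`T* = T0/(1 − x* k T0)`; a dense grid maximizer agrees to ≤0.01 K.
Mass–length conversions and control-chamber drift correction are
upstream of the package: inputs are corrected, averaged rates.

## Energetic efficiency

For each stream: feeding rate `F` from the field-setting parameters of
the winning functional-response model at the stream's prey density and
temperature; energy intake `F_E = F · M_S · E_S / 24` J/h (prey mass
`M_S = 0.546 mg` AFDM, energy density `E_S = 23.1 J/mg`; feeding stays
per-day, energy flows per-hour, harmonised only here); assimilation
`ω(T)`; metabolism `I` from the winning metabolic model at the stream
temperature and a configured representative predator mass (default the
mean respirometry mass — field individuals are unmeasured). Then
`y = ω F_E / I`; `y < 1` flags an energetic deficit. Measured routine
metabolic rates stand in for field rates (multiplier configurable,
default 1), and survey prey densities pass through a configurable
area-scaling factor (default identity) because the survey's per-m²
densities and the arena-scale attack coefficient have no published
reconciliation. Smooth summaries of `y` against temperature and against
predator abundance use penalized B-splines (statsmodels `GLMGam`),
falling back to a linear trend below five streams; their r² values are
descriptive summaries, not inference surfaces.

## Synthetic data: what it emulates

* **Feeding trials** — survivors are `Binomial(n0, N(t)/n0)` with
  `N(t)` from the depletion ODE; controls decline by mortality only;
  5% of predator arenas are flagged excluded (predator died/pupated).
  Default designs mirror the study: eight prey densities (2–60; the
  study's exact levels are unpublished, so these are configuration),
  laboratory temperatures {5,10,15,18} °C (2013) and {4,6,10,18} °C
  (2015), five field streams at {5,8,11,14,17} °C, per-cell replication
  chosen to match the study's arena totals (~240 fly arenas across
  three settings, ~300 caddis arenas across two), two controls per
  cell, 24 h duration.
* **Generating truths** are the published winning models: type II,
  setting-specific attack intercepts (fly 0.241/0.802/1.889; caddis
  1.529/5.515 per day at 10 °C), shared attack activation energies
  (0.704 / 0.229 eV), shared temperature-independent handling times.
  The printed handling times (4.033, 0.644) are interpreted on the
  hourly scale and converted to days: on a daily reading the response
  would saturate at ≤0.25 prey/day at every density, leaving the attack
  parameters unidentifiable — inconsistent with the precision the
  design demonstrably supports, whereas the hourly reading reproduces
  the reported standard errors almost exactly at the same replication.
  Background mortality is zero in the 2013 laboratory and
  `m0 = 0.10/day, E_m = 0.43 eV` in the 2015 settings (mortality was
  reported present in 2015 only; magnitudes are unpublished, these are
  realistic captive-prey values chosen once).
* **Respirometry** — lognormal noise around the published log-linear
  surfaces; σ_ln = 0.40 (fly) and 0.94 (caddis), calibrated once to the
  reported r² of 0.80 and 0.34 at the published designs (46 and 40
  records over {5,10,15,20,25} °C); masses log-uniform on 0.5–5 mg.
* **Streams** — 14 stream temperatures spread over 4–25 °C; prey
  abundance rising as `cap·f^1.5` of the thermal fraction toward the
  observed 8,500/m² maximum with lognormal noise; predator abundance
  increasing (fly) or hump-shaped near 10 °C (caddis).

What the generators do **not** emulate: electrode traces and drift,
block/spatial layout, multi-species prey mixtures, overdispersion
beyond binomial/lognormal noise, and temporal autocorrelation across
survey years. Passing recovery tests therefore demonstrate correctness
of the estimators under the assumed noise model, not robustness to
misspecification in real field data.

## Problem sizes used in tests and the acceptance run

Recovery of the shared attack activation energy uses 20–25 seeded
replicates of the full two-stage pipeline per predator with 4 optimizer
starts per fit; respirometry recovery uses 100–120 replicates;
BIC-structure selection is checked on a six-model representative subset
of the zoo over 3 replicates. These sizes keep Monte-Carlo error small
relative to the tolerances while the full suite completes in minutes;
the full 55-model zoo is exercised through the CLI (`--zoo-subset`
trims it for quick runs).

## Known limitations

* The likelihood family (binomial on eaten counts) is asserted, not
  estimated; overdispersed data would understate the standard errors.
* Mortality is plugged in, not jointly estimated; its sampling error is
  not propagated into the functional-response standard errors.
* Sharing structures assume the same response *type* across settings.
* The energetic-efficiency stage inherits every upstream point estimate
  without uncertainty propagation; its outputs are screening
  quantities, not confidence statements.
* With strongly saturated responses the attack intercept and activation
  energy are weakly identified; the Wald standard errors then degrade
  gracefully (reported large or flagged missing) but profile-based
  intervals are not implemented.
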