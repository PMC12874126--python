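# Methods

## Model

The package computes daily nutrient requirements for growing meat ducks by
the factorial principle — requirement = maintenance + production — extended
with dynamic corrections for season, temperature history, growth stage,
breed and amino-acid balance.

**Energy.**  `ME = SF·m·α_eff·W^0.75 + β_eff·BGW + T(ET, n) + BC` (kJ/d),
with W the live weight in kg, BGW the daily gain in g/d.  Metabolic body
weight W^0.75 is the standard allometric scaling of maintenance metabolism.
The temperature term is implemented in *deviation-from-threshold* form,

    T = γ(n)·k3_cold·max(0, t_low − ET)·W^0.75 − k3_heat·max(0, ET − t_high)·W^0.75,

rather than as a bare `k3·ET` product with a sign-switching coefficient.
A literal `k3·ET` with positive k3 would make ME *increase* with ET inside
the cold regime — the opposite of thermoregulatory compensation.  The
deviation form reproduces the intended sign pattern exactly (positive below
t_low, negative above t_high, zero inside the band), is continuous at both
thresholds, and scales with metabolic weight, since heat loss does.  This
is the package's one deliberate departure from the equation as printed, and
it is load-bearing: the sign-pattern and continuity invariants in the test
suite pin it down.

**Protein.**  `CP = a_z·W^0.75 + b_z·BGW + SF·AAI` (g/d).  The stored
coefficients are the winter/baseline values; in the heat zone the
maintenance coefficient is cut 18 % and the growth coefficient boosted
23 %, the seasonal coefficient shift identified by nonlinear regression on
production data.  The published protein constants are printed per kg live
weight; the implementation follows the equation's W^0.75 scaling and treats
the printed values as the W = 1 kg case, where the two coincide.

## Parameters, units, defaults

| parameter | unit | default | origin |
|---|---|---|---|
| α (maintenance energy) | kJ/(kg^0.75·d) | 541.7 | thermoneutral baseline |
| β (growth energy) | kJ/g | 19.86 | published growth requirement |
| SF | – | 1.35 / 1.15 / 1.05 | winter / transition / summer |
| k3_cold | kJ/(kg^0.75·°C·d) | 13.0 | anchored (below) |
| k3_heat | kJ/(kg^0.75·°C·d) | 8.0 | anchored (below) |
| t_low, t_high | °C | 15, 28 | thermoneutral band |
| γ table | – | 1 → 0.85, 3 → 0.51, 5 → 0.32 | lag damping by cold-spell length |
| rapid-growth threshold | g/d | 35 | adaptive reallocation trigger |
| α/β reallocation | – | −18 % / +24 % | rapid-growth coefficient shift |
| a (maintenance protein) | g/(kg^0.75·d) | 6.013 | published baseline |
| b (growth protein) | g/g | 0.18 | engineering default (protein content of gain); configurable |
| summer protein shifts | – | −18 % on a, +23 % on b | seasonal coefficient shift |
| AAI reference ratio | – | 3.0 | midpoint of the 2.8–3.2 lysine:methionine span |
| κ envelope | – | [0.12, 0.35] | breed seasonal sensitivity |

No published magnitude exists for k3.  The default k3_cold anchors the
theoretical +12 % maintenance compensation of a one-day cold spell at a
representative 5 °C deviation (0.12 × 541.7 / 5 ≈ 13); k3_heat is set
smaller because heat depresses intake less steeply than cold raises
maintenance.  Both are routine calibration targets and the defaults carry
no evidential weight.

γ(n) is a left-closed piecewise-constant step on the three tabulated
breakpoints (1.0 at n = 0, flat beyond n = 5).  Only three points are
published and the decay is described as nonlinear; a step function avoids
inventing a curve between them.  The damping applies to the cold branch
only, which is where the under-feeding lag is motivated.  The published
n = 1 row (0.85 × 12 % → 8.5 %) follows the product rule; the n = 3 row
prints 18.3 % where the product gives 18.36 % — the implementation computes
true products and treats the printed 18.3 as rounding.

Breed profiles store λ (basal metabolic coefficient), δ (temperature
sensitivity), κ, a deposition-efficiency ratio, an energy-difference
coefficient and a cold-season surcharge.  Parameters published as intervals
(κ ranges, 8–10 % surcharge, 12–15 % deposition deficit) are stored at the
interval midpoint with the interval kept as metadata.  The λ·δ product
scales the maintenance term (normalised so Cherry Valley = 1); BC stays a
separate additive offset.  How the multiplicative and additive breed
effects jointly act is not specified anywhere; this composition is the
package's choice and both are neutral for the baseline breed.

AAI's functional form is likewise unspecified beyond "a function of the
lysine/methionine ratio"; the package uses the normalised ratio
(lys/met)/3.0 — the simplest form that is 1 at the reference balance — and
exposes it as a plain function so an alternative index can be substituted.
The seasonal κ adjustment is symmetric multiplicative: ×(1 − κ) cold,
×(1 + κ) heat, matching the stated directions (more methionine in cold,
more lysine in heat).

## Known model properties and discrepancies

* The adaptive reallocation makes ME *discontinuous* in BGW at the 35 g/d
  threshold, and for heavy birds the −18 % maintenance drop can exceed the
  +24 % growth gain, so ME is monotone in BGW only within a growth regime.
* The published post-reallocation coefficient pair (0.44, 0.62) is not what
  −18 %/+24 % applied to the conventional pair (0.62, 0.38) gives
  (0.508, 0.471).  The implementation applies the stated percentages; the
  printed pairs are checked only through their own printed allocation
  ratios (1.63, 0.71).
* 6.013 × 1.35 = 8.118, not the printed winter value 8.138 (0.25 % apart);
  both constants are retained and a unit test asserts the computed 8.118
  with the 8.138 figure as a closeness reference.
* The 0.24 → 0.18 RMSE improvement is arithmetically 25 %, printed as 23 %;
  `error_reduction` computes true percentages.
* CP(winter) > CP(summer) on identical states holds throughout the
  maintenance-to-moderate-growth regime but *inverts* when the gain is
  large relative to metabolic weight, because the +23 % summer growth
  boost then dominates the winter maintenance excess.  Consequently the
  trajectory-mean CP of a full 42-day summer flock slightly exceeds the
  winter one under default growth; the winter excess is a
  maintenance-level property (8.118 vs 6.013 g/kg^0.75 at W = 1), and the
  tests assert it at that level.

## Calibration

The objective stacks ME and CP residuals, each standardised by the observed
standard deviation of its target, so two quantities three orders of
magnitude apart weigh equally: cost = Σ r².  Both optimisers are authored
here; `scipy.optimize.least_squares` serves only as an independent
cross-check in the test suite.

**Levenberg–Marquardt.**  Damping starts at 1e-3, ×10 on a rejected step,
÷10 on an accepted one (floored at 1e-15); the normal equations use
Marquardt scaling (λ·diag(JᵀJ)) with singular solves escalating the
damping; stop on relative cost change < 1e-8 or 200 iterations.  The
Jacobian is central finite differences on the vectorised predictor.  Steps
that would leave the valid parameter domain (e.g. a non-positive α) count
as rejected.  The best-found point is returned, so the final cost never
exceeds the initial one.  Standard errors come from σ²(JᵀJ)⁻¹ with
σ² = cost/dof.  An identifiability rank check on the Jacobian at the start
warns when the freed set is confounded given the data's breed/temperature
diversity (e.g. freeing k3_cold on all-thermoneutral data).

**Gradient descent.**  Full-batch, learning rate lr₀·decay^epoch
(defaults 0.001 and 0.95, the published schedule).  Descent runs in
coordinates scaled by the initial Jacobian column norms — per-parameter
learning rates, without which one global rate cannot serve coefficients
three orders of magnitude apart.  Ten consecutive cost increases abort
with a divergence diagnostic.  The published schedule is conservative for
this normalised objective; the recovery tests use lr₀ = 0.3 with decay 1,
which converges to machine precision on noise-free data within 300 epochs.

Degenerate inputs: a zero-variance target raises a configuration error
unless explicit scales are supplied (single-row data); an empty free set
returns the starting values as a converged zero-iteration result.

## Synthetic data

The generator emulates the record structure the model consumes: one house
temperature series shared by all birds, per-bird Gompertz growth
`W(t) = A·exp(−exp(−k(t − t_i)))` with lognormal heterogeneity on A
(CV 5 %), and observed ME/CP equal to the model-true requirement times
independent multiplicative Gaussian noise (requirements are positive and
heteroscedastic, so multiplicative noise is the natural error model).
Defaults: 200 ducks × 42 days, A = 3.2 kg, k = 0.08/d, inflection day 18
(peak gains ≈ 94 g/d, so the rapid-growth branch is exercised), scenario
means 8 / 21 / 31 °C for winter / transition / summer plus an annual
sinusoid, temperature noise SD 3 °C, observation noise 5 %.  A config plus
seed fixes every output byte.

What it does **not** emulate: feed intake behaviour, mortality, multi-house
temperature contrast, humidity effects, or any of the production
indicators the model does not consume.  Passing recovery tests therefore
demonstrate estimator correctness under the model's own assumptions, not
robustness to real-world misspecification.

**Conditioning of the cold coefficient.**  Under the default recovery
conditions the three free-coefficient Jacobian columns are mutually
correlated 0.84–0.93 (maintenance, growth and cold terms all ride on the
shared growth curve and the single house temperature series), and γ = 0.32
damping multiplies the cold signal on most winter days.  The k3_cold
estimator is unbiased (bias within 3 Monte-Carlo SEs over 20 seeds) but
carries a ≈ 8 % standard error at n = 200 × 42, so a single-run recovery
within 5 % holds only with roughly even odds across seeds; α and β recover
within 1 %.  Tightening k3_cold in practice requires temperature contrast
across houses, which the single-house generator deliberately does not
provide.

## Numerical conventions

* Season-zone boundaries are inclusive to the thermoneutral band (strict
  `< 15`, `> 28`).
* Worked-example comparisons round half-up to the printed decimals
  (feed-table convention), not banker's rounding.
* Energy unit is kJ throughout; printed maintenance constants of 0.545 /
  0.305 per kg W^0.75 are read as MJ-typos for 545 / 305 kJ, consistent
  with the 541.7 kJ baseline used everywhere else; 19.86 MJ/kg gain =
  19.86 kJ/g.  kcal↔kJ conversion uses 4.184.
* CSVs are comma-delimited UTF-8 with mandatory headers and fixed units;
  floats are written at 12 significant digits, making write→read round
  trips lossless at that precision.
* The default seed for stochastic paths is 20260112; every CLI run logs
  version, seed and config hash.

## Scope

Humidity is parsed and carried but never used (no published
parameterisation); random-forest coefficient fitting, economic analysis,
hybrid-breed heterogeneity correction and sensor integration are out of
scope.  The unnamed breed row with 107 % deposition efficiency is excluded
from the registry.
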