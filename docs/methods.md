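# Methods

## The scientific problem

When people choose between two items from different categories (say, a
chocolate versus an appetizer), they often hold a prior preference for one
category as a whole. That prior turns one option into a *default*: it is
chosen more often than the item-level values alone predict, and chosen
faster. `priorddm` implements the modelling pipeline that quantifies this
default bias and adjudicates between two mechanistic accounts within the
drift-diffusion framework — a shift of the accumulator's starting point
toward the default boundary, versus an extra drift component favouring the
default — together with an attentional variant in which gaze fixations
gate the momentary drift.

Two trial-level value covariates organize everything:

- `DV_IT = V_IT(def) − V_IT(alt)`, the item-level decision value
  (likeability rating of the default item minus the alternative item,
  rating units on a 0–100 scale);
- `DV_CAT`, the category-level prior preference (difference of the two
  categories' mean ratings; non-negative by the definition of the
  default).

## Diffusion model

The decision variable follows `dX = mu dt + sigma dW` between absorbing
boundaries at 0 (alternative) and `A` (default), starting at
`z = A/2 + S`; `S = 0` is an unbiased start. The response time is the
first-passage time plus a non-decision time `Tnd`. With
`k = 2 mu / sigma^2`,

    P(default)        = (1 − exp(−k z)) / (1 − exp(−k A))
    E[T | default]    = ( A coth(kA/2) − z coth(kz/2) ) / mu
    E[T | alternative]: substitute (mu, z) → (−mu, A − z)

both derived from the standard backward equations. As `mu → 0` these
reduce to `z/A` and `(A² − z²)/(3 sigma²)`; the implementation switches to
series expansions when `|kA| < 1e−6` (probability) or `|kA| < 1e−3`
(conditional mean, where the direct expression cancels catastrophically).
Exponents are clipped at ±500 and the strong-drift branches return the
asymptotic limits, so no parameter regime yields NaN. `sigma` is fixed to
1 during fitting (scale degeneracy with `A` and `mu`) and exposed for
simulation.

This is a moments-based ("EZ-style") treatment: only the choice
probability and the conditional mean RTs enter the likelihood, not the
full first-passage density.

### Monte-Carlo oracle

`simulate_paths` integrates the SDE by Euler–Maruyama. Plain endpoint
absorption tests carry an `O(sqrt(dt))` bias that exceeds three Monte-
Carlo standard errors at `dt = 0.5 ms` and 2×10⁵ paths, so each step also
applies the Brownian-bridge crossing probability
`exp(−2 (b − x_t)(b − x_{t+dt}) / (sigma² dt))` for each boundary `b`.
With the correction the simulator and the closed forms agree within MC
error across the tested drift/starting-point grid; the simulator is the
package's ground truth for validating the closed forms, never the other
way round.

### Attentional drift

In the attentional variants the momentarily unfixated option's value is
discounted by `theta ∈ [0, 1]`:

    mu = alpha * [ (V_def − theta V_alt) D_def − (V_alt − theta V_def) D_alt ] / (D_def + D_alt)

with `D` the total fixation durations. At `theta = 1` this reduces
exactly to `alpha * DV_IT` for any fixation pattern — the reduction that
makes the attentional models nest the plain ones.

## Model space

Every variant composes a *start rule* with a *drift rule*
(`model_space.ModelSpec`). Main experiment, seven models:

| name        | starting point      | drift                      | family |
|-------------|---------------------|----------------------------|--------|
| `null`      | 0                   | `alpha·DV_IT`              | null   |
| `s_free`    | one free shift      | `alpha·DV_IT`              | start  |
| `s_12free`  | one shift per opposition | `alpha·DV_IT`         | start  |
| `s_dvcat`   | `a·DV_CAT`          | `alpha·DV_IT`              | start  |
| `mu_const`  | 0                   | `alpha·DV_IT + b`          | drift  |
| `mu_12const`| 0                   | `alpha·DV_IT + b_block`    | drift  |
| `mu_dvcat`  | 0                   | `alpha·DV_IT + beta·DV_CAT`| drift  |

Eye-tracking experiment, four models: `null`, `sddm` (= `s_dvcat`),
`addm` (free `theta`, zero start), `asddm` (free `theta` + `a·DV_CAT`
start). "Per block" means per category opposition (12 of them): the
opposition is the unit at which the prior preference varies, and the
free-start-per-block model is what the start/DV_CAT correlation analysis
reads out.

`A`, `Tnd`, `sigma` and the RT noise SD are shared across blocks within a
subject. Parameters are fitted on an unconstrained scale: `log A`,
`log Tnd`, `log` RT-noise; the starting point passes through
`S = (A/2) tanh(2 S_lin / A)` so `|S| < A/2` always holds (near-identity
for small shifts; both the generator and the fitter use this same map);
`theta` maps through a scaled logistic into (0, 1.05) so estimates at or
slightly above 1 remain reachable. Priors are Gaussian on that raw
scale, weakly informative on each parameter's own natural scale: SD 0.1
for the per-rating-unit coefficients (`a`, `beta`; typical fitted values
are ~0.02), SD 1 for evidence-scale parameters (`alpha`, start shifts,
drift offsets) and for the log-transformed `A`, `Tnd` and RT-noise, and
mean 3.0 / SD 2 for raw `theta` (centred on `theta = 1`). The scaling
matters for model comparison, not just regularization: a prior that is
orders of magnitude wider than a parameter's natural scale vetoes the
parameter through its Occam factor alone (Bartlett's paradox) and would
hand the within-family comparison to the simpler model even on data
generated from the richer one.

## Inference

The likelihood of a trial is Bernoulli in the closed-form `P(default)`
plus a Gaussian density of the observed RT around the closed-form
conditional mean for the observed outcome, with a fitted noise SD shared
across trials. The Gaussian RT term is a deliberate simplification: the
first-passage distribution is right-skewed, and the fitted noise SD
absorbs the total RT variability. This is the natural observation model
for a moments-based forward model; it keeps every likelihood evaluation
closed-form and fast, at the cost of not exploiting RT-shape information.

Fitting is MAP by L-BFGS-B from five starts (a moment-matched heuristic
start, the prior mean, and seeded jitter around it — the per-block models
are mildly multimodal), followed by a finite-difference Hessian `H` of
the negative log-posterior at the optimum. The log model evidence is the
Laplace approximation

    log p(y) ≈ log p(y|θ̂) + log p(θ̂) + (d/2) log 2π − ½ log det H ,

exact-in-form because the priors are Gaussian in the fitted coordinates.
Posterior SDs come from the diagonal of `H⁻¹`. If `H` is not positive
definite the result is flagged and a BIC-style evidence
(`loglik − (d/2) log n`) substituted. Trials with non-positive RT are
excluded with a logged count; fixation-free trials are likewise excluded
for attentional models.

## Group-level model selection

`group_bms.rfx_bms` implements random-effects selection over the
subjects × models log-evidence matrix: population model frequencies get a
Dirichlet prior (concentration 1 per model), and a variational loop
alternates per-subject responsibilities
`u_nk ∝ exp(lme_nk + ψ(α_k) − ψ(Σα))` with the concentration update
`α = α₀ + Σ u`. Exceedance probabilities are always Monte-Carlo estimates
from 10⁶ Dirichlet draws (the K = 2 Beta-CDF closed form is kept out of
the implementation so it can serve as an independent test oracle).
Family comparison assigns each model a prior concentration of one over
its family size, equalizing prior mass across families, and sums
frequency samples within families. Two cautions worth knowing: adding a
constant to a subject's row leaves everything invariant (only evidence
differences matter), and with flat evidences the variational
responsibilities are prior-sensitive (a singleton family with per-model
prior 1 attracts responsibility away from models with prior 1/2), so
family xp values are meaningful only when the evidences actually
discriminate — which is the regime the analyses operate in.

## Behavioral statistics

*Choice bias* — logistic regression of choice (default = 1) on a constant
and the two option values centred at their grand mean, so the constant is
the log-odds of a default choice at a null decision value; the bias is
the implied `P(default) − 50%` in percentage points. Optional covariates:
`DV_CAT` (left uncentred, so the constant then reads as the residual bias
at null category preference — the attenuation analysis) and the lagged
choice (±1). Complete separation falls back to a ridge-penalized fit
(intercept penalized 10× more weakly) and is flagged.

*RT bias* — OLS of RT on `|DV_IT|`, choice type (alternative = 1) and
their interaction; the type coefficient is the bias (positive = default
faster). At least 3 trials of each type are required.

*Block-wise biases* — per-opposition intercepts with slopes shared across
the subject's 12 oppositions (penalized logistic with per-block
constants; OLS with per-block constants and per-block choice-type
effects). Twelve fully separate 36-trial fits are too noisy to recover
the choice/RT bias correlation at all (group r ≈ 0 in simulation); the
shared-slope estimator recovers it (group r ≈ 0.12–0.26 under the default
generator). Oppositions with fewer than two choices of either type are
dropped and counted. Per-subject Pearson correlations are t-tested
(two-tailed, one-sample) at the group level, as is every other group
statistic in the package.

*Bias by RT bin* — the choice-bias estimator applied within per-subject
RT quantile bins. A starting-point bias decays across bins (its influence
dilutes as accumulation runs longer); a drift bias does not. This is the
behavioural signature separating the two mechanisms.

*Fixation analyses* — per-trial fixation durations per option, last- and
most-fixated choice effects, 2×2 (chosen/unchosen × default/alternative)
duration cell means with a factorial ANOVA over subject-level cell means,
and fixation-proportion time courses locked to stimulus onset and to the
response (proportions need not sum to 1: gaze can be on neither option).
`gaze_to_fixations` turns raw 60 Hz gaze samples into fixation streams by
window membership and run-merging.

*Debriefing* — match rate between explicit category choices and
rating-derived preferences, and the correlation of stated confidence with
`|DV_CAT|`.

## Synthetic experiments

The generator (`synthetic_data`) emulates the study design end to end; by
default 24 subjects × 432 trials.

- **Ratings.** 3 domains × 4 categories × 36 items. Category means sit at
  45/52/59/66 (shuffled within domain per subject, subject-level jitter
  SD 3), item noise SD 10 truncated at ±2.5 SD, clipped to [0, 100],
  continuous by default (optional rounding to the 101-point scale). The
  7-point category spacing makes DV_CAT range ≈ 0–28 with mean ≈ 15, so
  that the default starting-point coefficient 0.02 (evidence units per
  rating unit — the scale of the weight the modelling recovers) yields a
  mean start shift of ≈ 0.3 = 15% of the boundary, i.e. a choice bias of
  ≈ 15% and an RT bias of a few hundred ms: the size of the effects the
  pipeline is meant to detect.
- **Design.** Per domain, categories are ranked by mean rating and the
  top two are opposed to the bottom two (oppositions 1–3, 1–4, 2–3, 2–4).
  Within an opposition every item is used once (hence twice across the
  design): half the 36 pairs take default-category items from the rank
  extremes and greedily match each with the unused alternative item that
  keeps the pair sum closest to the opposition mean (the value difference
  sweeps from strongly negative to strongly positive at a near-constant
  average); the other half pairs the remaining middle-rank items in
  rating order (minimal difference, average sweeping low → high). A
  deterministic swap pass then minimizes the pair-average /
  |pair-difference| correlation directly. Ties in ranks and category
  means break by item id / label. The orthogonalization is a typical-case
  property: for oppositions whose DV_CAT approaches the within-category
  spread, the feasible (average, difference) region is itself tilted and
  no pairing attains a low correlation — verified by exhaustive matching
  search on counterexamples. Trials are shuffled into 4 blocks of 9 and
  the default's screen side counterbalanced.
- **Behavior.** Choices/RTs come from Euler–Maruyama simulation
  (`dt = 1 ms`, bridge-corrected) of whichever model variant is the
  configured truth — the generator builds per-trial parameters through
  `model_space.trial_params`, so generator and fitter share one
  definition of every variant. Defaults: `alpha = 0.05` per rating unit,
  `A = 2`, `sigma = 1`, `Tnd = 0.35 s`, start coefficient `a = 0.02`,
  plus Gaussian RT noise (SD 0.1 s) resampled so RT > Tnd.
- **Fixations.** Alternating left/right fixations, first fixation left
  with probability 0.7, log-normal durations (median 300 ms, log-SD 0.5).
  For attentional truths the fixation process runs inside the diffusion
  loop and gates the momentary drift; otherwise streams are generated
  independently of the accumulator and truncated at the decision time.
- **Debriefing.** Softmax category choices on mean-rating differences
  (temperature 5 rating units) with confidence proportional to the
  difference plus noise.

What the generator does *not* emulate: sequential (history) effects,
rating drift between session halves, RT contaminants (fast guesses,
lapses), blinks/dropout in gaze streams, or item-level heteroscedasticity.
Passing recovery tests therefore shows the estimators are correct and
well-calibrated under the model's own assumptions and realistic effect
sizes — not that real data meet those assumptions.

## Numerical and design choices

- Stage seeds derive from the master seed by SHA-256 of
  `"{seed}:{stage}"` (first 4 bytes, masked to < 2³¹): independent but
  reproducible streams per pipeline stage.
- Optimizer: L-BFGS-B, `ftol = 1e−10`, 500 iterations, 5 starts
  (heuristic, prior mean, jitter SD 0.5).
- Finite-difference Hessian: central differences, relative step 1e−4.
- Likelihood clips `P(default)` to `[1e−12, 1 − 1e−12]`.
- The tanh start-squash carries a `(1 − 1e−9)` factor so saturated values
  stay strictly inside the boundaries.
- Exceedance probabilities: 10⁶ Dirichlet samples (≈ 0.0005 MC error);
  doubling the samples moves xp by < 0.002.
- Problem sizes in the validation suite: the oracle comparison runs
  2×10⁵ paths at `dt = 0.5 ms` over a 48-point grid; recovery runs 20
  seeded 24-subject experiments for the proportional-start model and 2 of
  them for the 16-parameter free-start model; model-selection recovery
  fits the full 7-model space to one start-biased and one null 24-subject
  experiment. These sizes give stable statistics while keeping the whole
  suite comfortably re-runnable on a laptop.

## Known limitations

- The Gaussian-RT observation model ignores RT skew; evidence values are
  therefore comparable across the variants fitted here but not against
  full first-passage-density likelihoods (Navarro–Fuss), and posterior
  SDs for RT-driven parameters are approximate.
- No across-trial variability parameters (`sv`, `st`, `sz`) and no
  hierarchical (cross-subject) priors.
- The additive-attention drift variant (attended-option bonus added to
  the drift rather than multiplicative discounting) is not implemented:
  no defining equation was available, and guessing one would change the
  model space being compared.
- Laplace evidence is asymptotic; for the 16-parameter per-block models
  on 432 trials the Occam penalty is approximate, which is exactly the
  regime the BIC fallback flags when the Hessian degenerates.
- Variational family-level BMS is prior-sensitive when evidences are
  flat (see above); report expected frequencies alongside xp when in
  doubt.
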