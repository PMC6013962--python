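# Methods

## Measurement model

A patient p with latent health value θ_p compares their own health with
a comparator health state i of value β_i, both on one unidimensional
scale; the response is Y_ip = 1 when the own state is preferred. The
model is the Rasch model with the person on the "ability" side:

P(Y_ip = 1 | θ_p, β_i) = expit(θ_p − β_i).

Its three standing assumptions — unidimensionality, monotonicity in
θ − β, and local independence of responses given θ_p — are inherited
unchanged. Sign conventions follow the health application throughout:
Y = 1 means "own health preferred", larger values mean better health,
and impaired states carry negative values relative to perfect health.
The Rasch difficulty/easiness vocabulary is deliberately avoided in the
interface.

Two parameterizations of the comparator values are provided:

* **Holistic**: one free β_i per comparator state (`fit_rasch_cml`).
* **Attribute-parameterized (LLTM)**: β_i = Σ_j Σ_{k≥2} α_jk d_jk(x_ij)
  with dummy indicators of the levels of a multi-attribute
  classification system (`fit_mapr_cml`). Level 1 of every attribute is
  the reference (α_j1 = 0), there is no intercept, and the design may
  additionally include products of dummies of two attributes
  (interaction terms). The model must have fewer free weights than
  fitted comparator states.

## Estimation

**Item side.** The raw score R_p = Σ_i Y_ip is sufficient for θ_p, so
item values are estimated by conditional maximum likelihood: the
conditional probability of a response pattern y given R = r is
exp(−Σ y_i β_i) / γ_r(ε), with γ_r the elementary symmetric function of
ε_i = exp(−β_i). γ_r and its leave-one-out and leave-two-out companions
(needed for the conditional margins and the information matrix) are
computed with the summation recursion in log space (`logaddexp`), which
is stable for item counts in the hundreds; the cheaper difference
algorithm is avoided as numerically unstable. Persons are grouped by
raw score so each distinct score is processed once.

The optimizer is damped Newton–Raphson started at β = 0 (α = 0),
maximizing the conditional log-likelihood; for the attribute model the
gradient and information are chain-ruled through the design matrix
(score_α = Wᵀ score_β, I_α = Wᵀ I_β W). Convergence requires
max |score| < 1e-8 (default, configurable) within 100 iterations. The
line search halves the step until the log-likelihood does not decrease
by more than 1e-12·max(1, |logCL|); the *relative* tolerance matters —
near the optimum of a well-fitting large sample the true gain of the
final Newton step sits below floating-point resolution of a
log-likelihood of magnitude ~10³, and an absolute threshold can
deadlock the search one step short of tolerance. Standard errors come
from the inverse of the conditional information matrix of the free
parameters.

**Identification.** The conditional likelihood is invariant to a common
shift of all β. The holistic fit is optimized with one item anchored at
0 and re-expressed under the requested anchoring: sum-to-zero centering
(default) or a chosen reference state at 0; the covariance matrix is
transformed accordingly, and every serialized fit records its
anchoring. The attribute model is anchored structurally by α_j1 = 0, so
the implied value of the all-reference state (perfect health) is 0
exactly. Holistic and attribute fits must be re-anchored to a common
reference before their values are compared; only differences are
meaningful across anchorings.

**Exclusions.** Persons with extreme raw scores (0 or I) carry no
conditional information and are excluded (flagged, and reported with
±∞ person values rather than a weighted-likelihood correction — plain
ML is the documented procedure). In the holistic fit, items whose
response column is constant over retained persons have no finite CML
estimate and are dropped with a warning; the reduction iterates because
each removal can create new extreme persons. In the attribute fit such
items are **kept**: through the shared weights and the raw-score
conditioning they still contribute information, and for realistic item
sets dropping them would leave rare severe levels without any
identifying item. Missing responses are rejected outright — no
missingness model is implemented, and informative missingness would
bias CML.

**Existence of estimates.** Finite holistic CML estimates exist iff the
response matrix is well conditioned: every bipartition of the items
into two non-empty sets has some person responding 1 in the first set
and 0 in the second. The check runs as a strong-connectivity test on
the directed item graph (edge i→j iff some person has Y_i = 1, Y_j = 0)
and returns a violating bipartition as a witness when it fails; tests
verify equivalence with brute-force bipartition enumeration. The
attribute model can remain estimable when the holistic condition fails
(the constraint couples items); identification is guarded instead by
requiring the design to have full column rank and the constant vector
outside its column span, with a singular-information error otherwise.

**Person side.** Given fixed item values, θ̂_p solves
R_p = Σ_i expit(θ − β_i) (unique root of a strictly increasing
function, found by Brent's method), with
se = 1/√(Σ_i P_i(1 − P_i)). Since x(1−x) ≤ 0.25, the standard error can
never fall below √(1/(0.25·I)); precision is best when comparators sit
near the person's own value, which motivates the adaptive design.

## Diagnostics

* **Andersen LR test**: persons split into score groups (default: raw
  score at or below the median vs above; arbitrary labels or a callable
  are accepted), item values fitted per group and pooled; statistic
  2[Σ_g logCL_g − logCL_pooled], df = (G−1)(I−1). Items constant within
  any group are dropped from all groups (logged), iterating until
  stable — the analogue of removing states that almost everyone judged
  worse. Monte-Carlo tests confirm the nominal 5% level is held within
  (3%, 8%) under the model.
* **Nested LR test**: 2(logCL_holistic − logCL_attribute) ~ χ² with
  df = (I−1) − #weights, valid only for identical data and item set
  (enforced by a data fingerprint). A saturated design (df = 0)
  reproduces the holistic fit exactly and is reported with statistic ≈ 0
  and p = 1. Replicates under an additive truth match the χ²(df)
  distribution.
* **Guttman scalogram**: persons sorted by raw score, items by column
  total, both descending; a cell is a misfit when it disagrees with the
  ideal staircase implied by the row's raw score (so a single swapped
  pair yields two misfit cells, and zero misfits is equivalent to a
  perfect Guttman pattern). Ties are broken by person/item id rather
  than input position, making the report canonical: permuting input
  rows or columns never changes the misfit count.
* **Person–item map**: histogram of finite person estimates next to the
  item locations on the shared scale, plus the fraction of
  (person, item) pairs with θ̂ > β̂.

## Prediction and agreement

With fitted attribute weights, any person with a self-classification
x̃_p gets the value f(x̃_p); under the adaptive variant θ_p may be fixed
to f(x̃_p) outright (an option, not the default). Predicted preference
for a comparator is 1 iff own value ≥ comparator value — ties predict
"prefer own", a deterministic convention required by agreement
statistics and documented because the model itself gives probability
one half at equality. Agreement with observed responses is summarized
by Cohen's kappa with a large-sample 95% CI (via statsmodels), labelled
per the usual benchmarks (> 0.75 excellent, 0.4–0.75 fair to good). A
degenerate table with chance agreement 1 yields an undefined kappa,
reported as such.

## Synthetic data

The simulator draws Y_ip ~ Bernoulli(expit(θ_p − β_i)) independently
(local independence by construction) and returns the generating truth
alongside the data. Seeding uses one master seed with per-person
substreams (`SeedSequence.spawn`), so identical scenarios are
byte-identical and enlarging the cohort never reshuffles earlier
persons.

Person-value families:

* `normal(loc, scale)`;
* `skewed`: θ = loc − scale·LogNormal(0, sdlog), a negated log-normal
  with a long tail toward poor health — patient value distributions are
  typically not normal;
* `own-state`: a self-classification is sampled per attribute from
  given level probabilities, and θ = f(x̃) + Normal(0, noise_sd).

The default scenario (`study_scenario`) reproduces the conditions of
the motivating empirical study: 163 patients, the same 17 fixed
EQ-5D-3L comparator states, item values implied by the study's
published main-effect weights, and `own-state` persons with level
marginals matching the study population and holistic noise sd 0.5. The
noise term is a modelling choice (the study reports no person-value
model): it separates a patient's holistic health from their five-digit
classification without overwhelming it. At this sample size the rare
severe levels are estimated with standard errors around 0.3–1.0, and
occasionally a simulated cohort gives a severe attribute level no
discordant response at all; such cohorts leave that weight essentially
unidentified (huge SE), exactly as the original study struggled with
its most severe states.

What the simulator does **not** emulate: response biases discussed
qualitatively in the field (adaptation, fatigue, presentation-order
effects), informative missingness, and dependence between attributes in
the own-state sampler (levels are drawn independently per attribute).
Passing recovery tests therefore show correctness of the estimators
under the model, not robustness of the method to violations of it.

The adaptive design is simulated by selecting, per person, the k bank
states closest in value to the person's own value (ties by bank order;
an optional balanced variant alternates picks above/below). A seeded
directional test confirms the adaptive design yields smaller mean
person-value SEs than an equally sized fixed spread-out design. The
ranking-task converter turns per-person best-to-worst orderings
(including an "own" card, optionally a "dead" card) into the binary
matrix: Y_ip = 1 iff state i is ranked below the own card; tied or
incomplete rankings are rejected rather than guessed at.

## Problem sizes used in tests

Structural and oracle tests run at I ≤ 12 against exhaustive
enumeration or refined grid search. Recovery experiments use
n = 2000 persons (17 items for the attribute model, 5 for the
holistic model); calibration uses 500 replicates of n = 300, I = 6 for
the Andersen level and 200 replicates of n = 300, I = 6 for the nested
LR null distribution; the end-to-end agreement pipeline runs at the
study's own n = 163. These sizes keep the whole suite around a minute
on one CPU while leaving Monte-Carlo error well inside the asserted
bands.

## Known limitations

* Values are relative positions on a logit scale; rescaling around
  "dead" for QALY/DALY use is out of scope, as are marginal-ML and
  Bayesian estimation, polytomous and multidimensional models, and
  item-level fit statistics (infit/outfit, DIF).
* Monotonicity of weights across levels is *reported*
  (`check_monotonicity`), not enforced; constrained estimation is out
  of scope.
* The delimited state-code variant (`"3-2-2-1-1"`) covers systems with
  more than nine levels per attribute; built-in presets exist only for
  the EQ-5D-3L.
* Complete response matrices are required; designs with structurally
  missing cells (beyond the per-person subsets of the adaptive variant)
  are not supported.
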