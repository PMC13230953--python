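# Methods

## The dual-memory model

A restudy trial strengthens the memory route formed at initial study; a
test-with-feedback trial strengthens that route *and* forms a second,
separate test-memory route. Three simplifying assumptions give the
quantitative model: (1) study-memory strength after training is identically
distributed for restudied and tested items; (2) study- and test-memory
strengths are identically distributed; (3) the two routes are
stochastically independent. Under (1)–(3) the probability of recall in the
test condition is the inclusive-or of two routes with common success
probability P_R, i.e. P_T = 2P_R − P_R², and the testing effect is
TE = P_R − P_R². Both generalise to subject-level proportions correct
(PC_R, PC_T), yielding a per-participant prediction with no free
parameters.

## The correlated-strengths extension

Relaxing assumption (3), route strengths are modelled as standard bivariate
normal with correlation ρ ∈ [0, 1] and an item is recalled when either
strength exceeds the threshold z = Φ⁻¹(1 − p) that alone yields recall
probability p — a Gaussian copula with identical marginals. This is the
minimal law that preserves identical marginals, nests independence at
ρ = 0 (reproducing the quadratic exactly), and carries a single correlation
parameter; other copulas satisfying the same constraints would give
slightly different interior values, so a ρ estimated under this law is
defined relative to it. Negative ρ is excluded: only positive dependence
between routes is theoretically motivated here.

The equal-coordinate orthant probability is evaluated exactly via Owen's T
function, Φ₂(z, z; ρ) = Φ(z) − 2·T(z, √((1−ρ)/(1+ρ))), vectorised over p.
This was cross-validated against scipy's bivariate normal CDF and an
adaptive double quadrature of the bivariate density (agreement < 1e-8; the
quadrature value at (0.47, 0.334), 0.6651646533, is frozen in the test
suite). Probabilities exactly 0 or 1 short-circuit (thresholds ±∞) instead
of evaluating Φ⁻¹ at the boundary. A Monte-Carlo estimator
(`correlated_pt_mc`, default 10⁶ draws, explicit seed, no global RNG
state) exists purely to validate the closed form.

A practical consequence asserted in the tests: the TE curve at ρ = 0.1
differs from the ρ = 0 curve by at most 0.016 anywhere in [0, 1], so small
route correlations are empirically indistinguishable from independence at
realistic sample sizes.

## Fitting ρ

The estimate minimises |mean_i f(pc_r_i, ρ) − mean_i pc_t_i| over ρ ∈
[0, 1], where f is the closed-form prediction evaluated at each
participant's own restudy proportion (not the group mean — the prediction
is a per-participant transform). The mean prediction is strictly
decreasing in ρ, so the minimiser is unique; bisection runs to 10⁻³ on ρ
(a 0.001-resolution grid search is available as a fallback method). If the
observed mean test accuracy already exceeds the independence prediction
the estimate is pinned at the ρ = 0 boundary (flagged in the result);
symmetrically at ρ = 1. Closed-form predictions are used inside the search;
the Monte-Carlo path is never used there, to keep the objective noiseless.

Because observed pc_r carries binomial noise at 40 items and f is concave
in p, the plug-in mean prediction is biased low by ≈ E[p(1−p)]/40, which
propagates to a small downward bias in the fitted ρ (≈ 0.02–0.03 at the
default design). Parameter recovery on 200 replicate cohorts (113
participants × 40 items, generating ρ = 0.334) gives a median estimate
within 0.05 of the generating value, and generating ρ = 0 yields a median
estimate of 0 (no spurious correlation); both are asserted in the suite.

The efficacy-reduction metric is (mean predicted TE − mean observed TE) /
mean predicted TE, with the prediction from the independent-routes model;
it is negative when testing outperforms the prediction.

## Cumulative distribution matching

PC_R and PC_T are sorted independently across participants (stable sort on
(value, participant id); ties are common since proportions are multiples
of 1/40) and placed on the quantile axis k/N, k = 1..N — equally spaced
with maximum 1, one point per participant. The predicted curve applies the
chosen transform to the sorted PC_R at each quantile. Deviation metrics
are computed on observed − predicted PC_T: mean signed, mean absolute, and
maximum absolute deviation. Cross-group comparison at matched quantiles
uses linear interpolation onto a common grid (default 101 points).

Because sorting preserves means, the mean signed deviation equals
mean(PC_T) − mean(2p̂ − p̂²), so even under independent-routes generation
it is not exactly centred at zero: Jensen's inequality on the concave
quadratic gives a positive offset of E[p(1−p)]/n_items (≈ +0.005 at 40
items), an order of magnitude smaller than the overprediction signature
produced by ρ = 0.334 generation (≈ −0.04). The suite asserts the replicate
mean matches this analytic offset rather than testing it against zero.

`range_fraction` reports the share of participants with PC_R in a band
(default 0.4–0.6, where the quadratic TE peaks). The band is treated as a
closed interval; because "between 0.4 and 0.6" is ambiguous for values
exactly at the edge (possible with 40-item proportions: 16/40, 24/40), the
report carries both closed- and open-interval fractions.

## Inference

The 2×2 mixed ANOVA (one within-participant pair of measures × one
between-participant group) delegates to `pingouin.mixed_anova`; the test
suite checks it against a hand-computed cell-means sums-of-squares
decomposition on small balanced designs. Unbalanced groups are handled by
the standard mixed-design decomposition. When the two within measures are
identical for every participant the within and interaction strata are 0/0;
the zero-effect limit (F = 0, p = 1) is returned. Degrees of freedom use
complete cases (every participant must have both measures).

t tests are two-sided; paired tests equal a one-sample t on difference
scores. Zero-variance input with zero mean difference returns the
no-effect limit t = 0, p = 1; zero variance with a nonzero difference
raises an error rather than reporting an infinite statistic — proportion
data pinned at floor or ceiling can genuinely produce this, and an
explicit error is more honest than ±∞.

The JZS Bayes factor for t statistics uses the default Cauchy prior
(scale 0.707) on standardised effect size, computed by one-dimensional
quadrature over the inverse-gamma mixing representation; it is
cross-checked in the suite against pingouin's independent implementation
(relative agreement 10⁻⁶). Raftery evidence labels bin the directional
Bayes factor max(BF10, BF01) into half-open intervals closed on the left:
[1, 3) weak, [3, 20) positive, [20, 150) strong, ≥ 150 very strong — the
conventional ranges overlap at the endpoints, so the left-closed convention
is fixed here and documented. ANOVA-effect Bayes factors are *not*
implemented: the default mixed-model BF requires multidimensional
integration over random-effect priors, and the report labels them out of
scope.

## Synthetic cohorts

The generator emulates the target design: two relatedness groups
(defaults 118 low / 113 high participants), restudy vs test within
participants, 40 items per condition, 0/1 outcomes on a delayed cued-recall
test. Per-participant ability p_i follows a Beta law with group mean and
concentration κ (shapes mean·κ and (1−mean)·κ); defaults are mean 0.47
(high) / 0.30 (low) with κ = 4, wide enough that observed PC_R spans
essentially the full unit interval. The concentration is a free modelling
choice — the emulated study reports no ability variance — documented here
and in the config, not an estimate. A `point` law (degenerate at a given
p) supports exact checks. The same p_i drives both training conditions
(assumption 1 enforced); test outcomes are scored from a correlated
bivariate-normal strength pair, so their expected accuracy is the
closed-form correlated prediction. Items are exchangeable by default; an
optional per-item additive effect on the probit scale
(`item_effect_sd > 0`) is available but off, since item-level analysis is
out of scope. All randomness flows from the config seed; identical configs
reproduce byte-identical tables.

What the generator does **not** emulate: spelling/scoring noise (inputs
are assumed pre-scored), item-difficulty structure tied to associative
norms, training-phase dynamics (feedback timing, forward testing effects),
or retention-interval forgetting. Passing tests therefore demonstrate the
analysis chain's correctness under the stated generative model, not the
behavioural adequacy of that model for any particular real dataset.

## Problem sizes and numerical choices

Simulation-based checks use 200 replicate cohorts for parameter recovery
and the overprediction signature, 2000 replicates for type-I-error
calibration, 10⁵–10⁶ Monte-Carlo draws for oracle equivalence, and
1001–10⁶-point grids for the closed-form identities; these sizes keep the
statistical assertions sharp (3-SE bounds, ±0.013 calibration bands) while
the full suite runs in about a minute. Bisection tolerance on ρ is 10⁻³;
closed-form identity tolerances are 10⁻⁶. The pipeline report is a
pydantic model whose JSON schema ships with the package
(`report.schema.json`); reports validate against it at load time.

## Known limitations

- ρ is identified only through the mean (one moment); distribution-level
  fit at the estimated ρ is emergent and should be inspected via the
  deviation metrics, not assumed.
- The Gaussian-copula law is a reconstruction of "correlated strengths";
  estimates under a different dependence law would differ slightly.
- The plug-in fit inherits the small finite-items attenuation described
  above; at 40 items it is well inside the recovery tolerance, but designs
  with very few items per condition would need a correction.
- Single-group data support the per-group stages only; between-group
  ANOVAs require both groups.
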