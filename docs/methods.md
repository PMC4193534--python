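# Methods

## Model

A population of size *n* is screened with two dichotomous tests applied
simultaneously; anyone positive on either test is verified with a gold
standard assumed perfect, double-negatives are never verified. The
unknowns are the prevalence π, the test accuracies Se₁, Se₂, Sp₁, Sp₂ and
the conditional covariances CovD⁺ = Cov(T₁,T₂ | D⁺), CovD⁻ = Cov(T₁,T₂ | D⁻),
which capture the within-class dependence of two tests with a shared
biological basis. The covariances are restricted to their nonnegative
feasible ranges, 0 ≤ CovD⁺ ≤ min(Se₁,Se₂) − Se₁Se₂ and
0 ≤ CovD⁻ ≤ min(Sp₁,Sp₂) − Sp₁Sp₂; within them every stage-one cell
probability is automatically nonnegative.

The likelihood is the product of two multinomials: the stage-one
cross-classification (x₁₁, x₁₀, x₀₁, x₀₀) over the dependence-adjusted
cell probabilities, and the stage-two verification vector (a₁₁, a₁₀, a₀.)
over (π·Se_JE, (1−π)(1−Sp_JE), π(1−Se_JE) + (1−π)Sp_JE), with
Se_JE = Se₁ + Se₂ − (Se₁Se₂ + CovD⁺) and Sp_JE = Sp₁Sp₂ + CovD⁻ the
accuracy of the "either positive" joint rule. Two facts about this
formulation matter for interpretation:

* the stage-two vector shares margin information with stage one
  (a₀. = x₀₀ and a₁₁ + a₁₀ equals the joint-positive total), so the
  positive/negative split enters the likelihood twice. This is the model
  as defined and fitted; `log_likelihood(..., factorized=True)` exposes
  the non-redundant alternative (stage-one multinomial × binomial split of
  the verified subjects) for sensitivity analysis. In the perfect-test
  limit the product form yields a Beta(2k+1, 2(n−k)+1) prevalence
  posterior versus Beta(k+1, n−k+1) for the factorized form; the test
  suite checks both against their exact posteriors.
* multinomial constants (log factorials) are kept in the stored per-draw
  log-likelihood so deviance summaries are comparable across model
  variants on the same data.

Sequential-testing accuracy (screen *and* gold standard positive) is
Se_JB = Se_JE·Se_GS and Sp_JB = 1 − (1−Sp_JE)(1−Sp_GS); the gold-standard
constants default to 1 and are never sampled.

## Priors

Identifiability comes from probabilistic constraints, not model pruning.
Sensitivities receive two-step hierarchical uniforms Seᵢ ~ U(aᵢ, bᵢ),
bᵢ ~ U(b₁ᵢ, b₂ᵢ): the analyst commits only to a lower bound (usually easy
to defend from kit documentation or prior studies) and lets the upper
bound be diffuse. Specificities and prevalence are U(0,1); covariances are
conditionally uniform on their feasible range given the accuracies, with
the range-dependent normalization included in the joint density. Setting
`dependence=False` fixes both covariances at zero (the conditional
independence variant). Beta priors are deliberately not offered: ranges
are the elicitation currency here.

The bundled worked example uses Se₁ ~ U(0.5, U(0.55, 0.99)),
Se₂ ~ U(0.6, U(0.65, 0.99)), matching the elicitation that the Hemoccult
sensitivity is at least 0.5 and the RPHA-Hemeselect sensitivity at least
0.6 with diffuse upper bounds.

## Sampler

All unknowns — the five probability parameters, the latent two-step upper
bounds, and the two covariances — are mapped to a unit hypercube:
plain-uniform parameters by an affine map, a two-step pair (se, b) by
b = b₁ + w(b₂−b₁), se = a + u(b−a), and each covariance by u·B(accuracy).
In these coordinates the joint prior is exactly flat (the hierarchical and
range-dependent normalizations cancel against the change-of-variables
Jacobians), the support is fixed, and the target density is the likelihood
alone. Each coordinate is logit-transformed to ℝ (adding the standard
log u(1−u) Jacobian) and updated one at a time by a Gaussian random walk.

Proposal scales adapt by Robbins–Monro (step t^−0.6) toward 0.44
acceptance per coordinate during burn-in only, so post-burn-in transitions
are exactly Markov with the correct stationary distribution. Chains start
from independent prior draws (uniform on the cube), seeded; a run is fully
determined by `(seed, chain index)` via a seed sequence. Defaults are 2
chains × 105,000 iterations with 5,000 burn-in (the length used for the
reported worked-example posteriors; the colorectal fit takes ~10 s per
chain). Split-chain potential scale reduction and effective sample size
(via arviz) are attached to every summary; R̂ > 1.05 on a headline
parameter raises a warning, not an error. Derived quantities (Se_JE,
Sp_JE, PPV_JE, ρD⁺, ρD⁻) are computed per draw and summarized by their
posterior median and central 95% interval — never by transforming
summarized base parameters, since medians do not commute through nonlinear
maps.

## Model checking

Because the double-negative cell is unobserved, no single diagnostic
suffices; four are combined:

1. **pD / DIC**: D(θ) = −2 log L(θ); pD = mean deviance minus the deviance
   at the posterior mean of the seven base parameters on their natural
   scale (the mean covariance is clipped into the feasible range at the
   mean accuracies if needed); DIC = mean deviance + pD. A pD near the
   number of effective unknowns indicates the priors restored
   identifiability; a *negative* pD flags a non-identified fit (it occurs
   systematically when only the specificities are informative at low
   prevalence). "Reasonable" is operationalized as
   pd_min < pD ≤ pd_max with defaults (0, number of sampled unknowns],
   configurable.
2. **Local χ² posterior predictive p-value**: per retained draw θ,
   T(y; θ) = Σ (O − np(θ))²/np(θ) over the six *known* cells
   (x₁₁, x₁₀, x₀₁, x₀₀, a₁₁, a₁₀ — a₀. duplicates x₀₀ and is excluded);
   one replicate dataset is drawn from the two multinomials at each θ and
   ppp = P(T(y_rep) ≥ T(y_obs)). Near-zero expected cells (< 1e−12) are
   skipped. Pass band defaults to [0.05, 0.95].
3. **PPV coverage**: the observed verified fraction a₁₁/(a₁₁+a₁₀) should
   fall in the 95% credible interval of PPV_JE.
4. **Cell coverage**: each known cell's observed count should fall in its
   95% posterior predictive interval; by default at most one cell may
   fall outside.

Overall pass requires all four. Replicates are generated once per retained
draw with a vectorized sequential-binomial multinomial sampler, seeded
independently of the fit.

## Synthetic data

`simulate_counts` draws the latent 8-cell disease × T₁ × T₂ multinomial
(cell masses π·P(pattern | D⁺) and (1−π)·P(pattern | D⁻) with the same
covariance structure as the likelihood) and collapses it, so the generated
x and a vectors are internally consistent by construction and the
generator shares no code path with the likelihood it is used to test. It
emulates exactly the design's sampling process — simple random sampling,
simultaneous testing, verification of screen-positives by a perfect gold
standard. It does *not* emulate imperfect verification, verification
refusals, borderline/indeterminate test results, or covariate
heterogeneity in accuracy; passing recovery tests therefore speak to the
estimator under the design's own assumptions, not to robustness against
those violations.

Scenario presets encode the two study regimes — (π, n) = (0.01, 20 000)
for community screening and (0.40, 200) for clinic populations, each with
a high-accuracy pair (0.90/0.95, 0.95/0.90) and a low-accuracy pair
(0.60/0.70, 0.70/0.60) — with conditional correlations ρD⁺ = 0.5,
ρD⁻ = 0.4 converted to covariances by inverting
ρ = Cov/√(Se₁(1−Se₁)Se₂(1−Se₂)). Prior modes reproduce the tabulated
pairings of true values with informative one-step, two-step, and flat
priors. The dependent/independent misspecification comparison uses a
moderate truth (π = 0.1, Se = 0.7/0.8, Sp = 0.8/0.7) at n = 2000, a size
chosen to sit between the two preset regimes.

The scenario runner reports per-replicate posterior medians, 95% interval
coverage of the truth, and pD/DIC per model variant. Replicated-table
point values from single unseeded datasets are not reproducible, so the
simulation study is validated through properties: interval coverage ≥ 80%
under two-step sensitivity priors, negative pD under
specificities-only information at low prevalence, and larger DIC for the
independence model on dependent data. The acceptance-level tests run these
with 12/6/6 replicates at 20,000-iteration single chains; the runner
supports arbitrary replicate counts.

## Numerical notes and limitations

* Cell probabilities are algebraically nonnegative inside the feasible
  covariance region; the likelihood still guards against p ≤ 0 with a
  positive count and returns −∞ rather than raising.
* Conditional correlations are reported as NaN when an accuracy sits
  exactly at 0 or 1 (undefined denominator), not as an error.
* The printed point value of the local χ² statistic is reported as the
  posterior median of T(y_obs; θ); only the p-value participates in the
  verdict.
* `MCMCConfig.n_iterations` is the total per-chain length including
  burn-in; retained draws = (n_iterations − n_burnin)/thinning per chain.
* Single-site random-walk updates are adequate here (9 coordinates, cheap
  likelihood) but would mix slowly for strongly correlated posteriors at
  much higher dimension; no gradient-based sampler is provided.
* With flat sensitivity priors the model is effectively non-identified:
  posteriors for Se₁, Se₂ stay near-prior-wide and the prevalence drifts
  upward. This is a property of the problem, reproduced (and tested) here,
  not a sampler failure.
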