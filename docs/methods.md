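# Methods

This note documents the statistical machinery in `catia`: the model, the
estimation and screening procedures, the numerical choices, what the
synthetic-data generator does and does not emulate, and the limits of what
the test suite demonstrates.

## Model and scoring

All items are 5-category graded-response (GRM) items: cumulative boundary
probabilities are 2PL logistics `P*_k(θ) = expit(a(θ − b_k))`, category
probabilities are their successive differences, and item information is
Samejima's `I(θ) = Σ_c (P′_c)²/P_c` with
`P′_c = a[P*_c(1−P*_c) − P*_{c+1}(1−P*_{c+1})]`. Scores are 1–5 in files
and 0–4 internally; the conversion happens only at the I/O boundary so the
likelihood code has a single coding.

θ is estimated by EAP — the posterior mean under an N(0, 1) population
prior — and its standard error is the posterior SD, not an
information-based approximation. This matters: the reported conditional
standard errors (CSEE) and marginal reliabilities are statements about the
posterior SD. Likelihoods are accumulated in log space and always in bank
order, so the estimate is invariant, bitwise, to the order in which items
were administered; the adaptive engine's final estimate therefore equals
non-adaptive full-bank scoring of the same responses exactly.

**Quadrature.** The default grid is 81 equally spaced nodes on [−4, 4]
with standard-normal weights, endpoint weights halved (trapezoid rule) and
the whole vector renormalized. The trapezoid correction is what makes
posterior moments converge quadratically in the node spacing; with it, the
81-node EAP agrees with 10,001-node brute-force integration to better than
1e−4 in both θ̂ and SE across random response patterns, including extreme
ones whose posterior touches the grid boundary. Node count and range are
configurable everywhere.

## Calibration (MML-EM)

Item parameters are estimated by marginal maximum likelihood with a fixed
quadrature prior. The E-step computes each person's posterior weights over
the nodes; the M-step maximizes each item's expected complete-data
log-likelihood by L-BFGS-B with analytic gradients. Slopes are optimized
as `log a` and thresholds as `(b1, log-increments)`, which enforces
`a > 0` and strict threshold ordering by construction rather than by
post-hoc sorting. Convergence is declared when −2LL changes by less than
1e−4, with a 500-cycle cap; hitting the cap flags the result instead of
failing silently. Items with a single observed category are rejected by
name — their thresholds are not identified. Starting values come from the
observed cumulative category proportions (logit transform, minimum gap
0.05).

At the bank-construction scale (20 items, n = 1,000) the EM recovers
generating parameters with corr(a_true, a_hat) ≈ 0.96 and threshold RMSE
≈ 0.07–0.12, converging in ~50 cycles in about a second.

## Bank-construction QC

The pipeline runs the six screens in order — unidimensionality, local
independence, monotonicity, DIF, item fit, discrimination — recalibrating
after every exclusion wave and repeating until a full pass excludes
nothing (a fixed point; re-running the pipeline on its own output is a
no-op). Design choices where the procedure itself left room:

- **EFA screen.** Pearson correlations of the raw 1–5 scores, eigen
  decomposition, loadings `√λ₁ · v₁` (sign fixed positive). Polychoric
  correlations would be the natural refinement but are not implemented.
  Note an identity worth knowing: an item's first-factor loading is
  approximately `(a/1.702)/√(1 + (a/1.702)²)`, so the 0.4 loading cut
  implicitly removes items with a below roughly 0.77 — which is why the
  later discrimination filter (a ≥ 1) rarely fires on anything the
  loading screen let through, and why a pool's genuinely weak items are
  usually recorded under `unidimensionality`.
- **Q3.** Residuals `x_j − E[x_j | θ̂]` at the EAP estimate, expected
  scores from the calibrated GRM; pairs with Q3 > 0.36 are flagged and
  the member with the lower Mokken item H is excluded (ties: lower a,
  then lexicographically smaller id). Zero-variance residuals make a pair
  explicitly "undefined" rather than silently zero.
- **Mokken H.** `H_jk = cov/cov_max` with the maximum covariance given
  the margins obtained from the comonotone (sorted) joint distribution;
  item and scale coefficients are the matching ratios of sums. Perfect
  Guttman data gives H = 1 exactly; independent items give H ≈ 0.
- **S-X².** Observed vs expected category frequencies within summed
  rest-score groups; expected frequencies integrate the Lord–Wingersky
  score distribution of the remaining items against the prior. Rows are
  merged until each carries at least 5 expected observations, then cells
  under 1 expected merge into their neighbor; df = (cells − rows) − 5.
  The recursion is verified against exhaustive enumeration, and the
  statistic's type-I rate at α = 0.01 sits near (slightly below) nominal
  on model-conformant data.
- **DIF.** Proportional-odds cumulative-logit models via statsmodels'
  `OrderedModel`, matching on the EAP θ̂ from the current surviving bank
  (single pass, no purification iterations). McFadden R² uses the
  closed-form intercepts-only null. The flagged contrast is M1 (θ̂) vs M3
  (θ̂ + group + interaction), i.e. total DIF; uniform/non-uniform splits
  via M2 are available as optional output. Within a wave, DIF runs before
  item fit so a group-dependent item is attributed to DIF rather than to
  marginal misfit.
- **Discrimination.** `a < 1.00` on the calibrated bank. Because the
  filter sees *estimated* slopes, a genuine item whose true a is just
  above 1 can occasionally fall to it through sampling noise at n ≈ 1,000.

## Adaptive administration

Random uniform first item (seeded) for exposure control; EAP update after
every response; stop check (SE ≤ threshold) immediately after the update,
with a minimum of one item even when the prior SD already satisfies a
loose rule; MIC selection of the next item with exact-tie resolution
toward the smaller item id. No maximum length other than bank exhaustion
(a `max_items` option exists but defaults off), no content balancing, and
no exposure control beyond the random start — for Likert-type clinical
scales there is no answer key to leak, so heavier exposure machinery buys
little.

## Evaluation

Overall CSEE/CBIAS/CMAE/CRMSE are person-level means across all simulees
(not means of bin means, which would over-weight sparsely populated
extreme-θ bins); per-bin curves default to width-0.5 bins on [−4, 4] and
report empty bins as missing. Marginal reliability is `1 − (mean SE)²`.
AUC uses the rank (Mann–Whitney) formulation with tie half-credit —
checked exactly against pairwise enumeration — with a Hanley–McNeil 95% CI
by default and DeLong as an option; the diagnostic cut-off maximizes the
Youden index over midpoints of consecutive sorted estimates, resolving
ties toward higher specificity. Diagnostic rules follow the source
questionnaires: a strict sum > 39 on the IAT items, and "at least 4 of the
designated items scored 4 or 5" for GAS-style criteria (the designated
subset is a parameter, since the instrument does not enumerate it).

## Synthetic data

The generator emulates the study's data regime: θ ~ N(0, 1); slopes
uniform on [1.1, 2.6] and thresholds spanning roughly [−2, 3.5], matching
the packaged bank's span; two-level covariates at the survey's rates
(50.2% female, 58.9% rural; 35% under 18, a choice consistent with the
sample's mean age of ~18.7); and a diagnosis label `θ > 0.5` (≈30%
prevalence, in line with reported rates in student populations) flipped
with 5% label noise. Planted defects target one screen each; the default
effect sizes (DIF threshold shift 0.8, dependent-pair copy with 10%
re-draw, low slope 0.6, uniform-noise items) give ≥ 80% detection at
n = 1,000, the regime the pipeline is meant for. All draws flow from
seed-derived substreams, so identical designs reproduce bit-identical
data.

What the generator does **not** emulate: item-level skew and floor effects
of real survey scores, multidimensional symptom structure beyond a single
planted second factor, missing responses, and careless-responder
artifacts. Passing tests therefore demonstrate that the machinery is
correct and well-calibrated under the model's own assumptions — not that
real questionnaire data will be as clean.

## Problem sizes and reproducibility

The test suite and acceptance script use the study's own scales where they
are cheap — 1,000 simulees for Monte-Carlo sweeps and calibration
recovery, 16-item pools with n = 1,000 for pipeline sensitivity (20 seeds)
— and smaller populations (a few hundred) for trend and smoke checks. The
packaged bank's published parameters are used as-is; re-deriving them
would require the original 1,368-person survey responses, which were never
released, so the real-data tables (bank construction exclusions,
efficiency on observed responses, validity coefficients) are represented
here by their arithmetic identities and by synthetic-data properties
instead. Every stochastic component takes a seed, and all CLI outputs
embed a hash of the effective configuration.
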