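# Methods

## Model

All measurement is under the Partial Credit Model.  Person *v* at latent
location θ_v (logits) responds to item *i* (categories 0…m_i) with

    P(X_vi = k) = exp( D Σ_{j≤k} (θ_v − δ_i − τ_ij) ) / Σ_h exp( D Σ_{j≤h} (θ_v − δ_i − τ_ij) )

with item location δ_i, within-item-centred thresholds τ_ij
(Σ_j τ_ij = 0), and scaling constant D.  The model is an exponential
family in θ: the score is D(x − E[X|θ]) and the Fisher information
D²·Var(X|θ), additive over items.  D defaults to 1.0 during calibration
(the usual logit metric) and 1.7 inside the CAT engine (normal-ogive
approximation); it is applied only at simulation/administration time,
never twice.

Identification: the latent density is standard normal during estimation;
fitted item locations are re-centred to mean zero afterwards (the report
records the shift, which relocates the latent origin by the same amount),
and thresholds are centred within item.

## Item calibration

`fit_pcm` maximises the marginal likelihood by Bock–Aitkin EM:
49 Gauss–Hermite nodes approximate the N(0,1) latent density, the E-step
forms posterior node weights per person, and the M-step runs a damped
Newton ascent per item on the cumulative step difficulties (gradient and
Hessian in closed form; the Hessian is negative definite).  Convergence is
declared at a relative log-likelihood change below 1e−6 (cap 500
iterations, warning on non-convergence); the EM trace is non-decreasing by
construction and asserted in tests.  Missing responses are
missing-at-random: the likelihood runs over observed cells only.  An item
category observed zero times raises a structured error naming the item and
category — a model with a null category is not identified and silently
compressing codes would corrupt scoring maps.  Parameter standard errors
come from the empirical (cross-product) information of the per-person
marginal scores.

Person scoring (`estimate_person_locations`) solves the ML or Warm
weighted-likelihood (WL) equations by vectorised damped Newton; WL adds
J/(2I) to the score with J = D³ Σ_i μ3_i (the derivative of the test
information), stays finite at floor/ceiling patterns, and is the default
throughout.  Persons with extreme raw scores are flagged; when ML is
requested for them the WL value is substituted (ML diverges).
SE(θ̂) = 1/√I(θ̂).  The Person Separation Index is
(Var θ̂ − mean SE²)/Var θ̂ over non-extreme persons.

## Screening battery

*Mokken scalability.*  Loevinger's H computed from covariances against the
comonotone maximum with the observed marginals (equivalently, weighted
Guttman errors against their expectation under independence): H_ij =
cov(X_i,X_j)/covmax(X_i,X_j), item H_i the covariance-weighted aggregate,
scale H over all pairs.  Items with H_i below .3 (configurable) are
removed in one pass before any parametric fitting.  Monotonicity is
checked on rest-score groups (minimum size n/10, adjacent groups merged);
each decrease in mean item score carries a z statistic so sampling noise
can be ignored.

*Residuals.*  z_vi = (x_vi − E[X|θ̂_v])/√Var[X|θ̂_v], extreme persons
excluded.  Because θ̂ is estimated from the same responses, E[z²] is
deflated by roughly (1 − h_vi) with h_vi the item's share of the test
information at θ̂_v; fit statistics therefore use the leverage-adjusted
squares z²/(1 − h).  Without this adjustment the null fit-residual
distribution centres near −1; with it the simulated null is mean ≈ 0.04,
SD ≈ 1.03.

*Item fit.*  Persons are grouped into five equal-count class intervals by
θ̂ (merged below 20 persons per interval); the chi-square compares
observed and expected interval score sums with variance weighting,
df = intervals − 1, flag at P < .01.  The fit residual is a
Wilson–Hilferty cube-root normalisation of the mean adjusted squared
residual, flagged outside ±2.5.  The transform assumes chi-square-like
dispersion of z²; polytomous residuals are lighter-tailed, so the
statistic is slightly conservative — acceptable for a screen.

*Disordered thresholds.*  An item is disordered when any adjacent
estimated τ pair reverses.  Repair merges the squeezed category downward
(a five-category item disordered between thresholds 3 and 4 rescores
1-2-3-4-5 → 1-2-3-3-4); an optional semantic partition of the response
anchors blocks merges across a neutral boundary.  Rescoring precedes any
removal within an iteration — it is a repair, not a deletion — and always
triggers a refit.

*Local dependency.*  Pearson correlations of residual columns; pairs with
r above the cutoff are flagged.  Default cutoff +.20, with .10 available —
both conventions circulate, and the signed positive form is used because
negative residual correlation is the benign by-product of conditioning on
the total.

*DIF.*  Per item and factor, a two-way ANOVA of residuals on factor
(uniform DIF) and factor × class-interval (non-uniform DIF), Bonferroni
over items.  Simulated null rates at α=.05: main effect 4.7%,
interaction 5.9% (mildly inflated by the discreteness and skew of
polytomous residuals in extreme intervals; a variance rescale does not
remove it), combined 5.3% — within one sampling SD of nominal.  The
Bonferroni step makes false removals in the loop rare regardless.

*Unidimensionality.*  Items split by loading sign on the first principal
component of the residual correlation matrix; each person's θ is
estimated separately from the two subsets (WL) and compared with
t = (θ̂_A − θ̂_B)/√(SE_A² + SE_B²).  Reported: percent |t| > 1.96 with a
Wald binomial 95% CI; the scale is judged multidimensional when the CI
lower bound exceeds 5%.  On one-dimensional data the raw percent hovers
around 5–7% (the SEs are finite), which is why the CI rule rather than the
raw percent drives the verdict.

## Calibration loop

Order of operations: one-shot Mokken screen → { fit PCM → repair
disordered thresholds (refit) → diagnostics → remove exactly one worst
offender } until clean.  Removal priority: local dependency (the pair
member with the worse absolute fit residual) before fit residuals before
chi-square misfit before DIF — dependency distorts every other statistic,
so it is resolved first.  The loop never drops below `min_items` (it
aborts with status "criteria not met"), refuses to revisit a previously
seen item set (oscillation guard), and replays byte-identically from
(data, config).  The report carries audit-summary initial/final rows: item
and person fit-residual means/SDs, total chi-square with df and P, PSI,
percent extreme scores, and the t-test percent with CI.

## Adaptive testing engine

EAP scoring integrates prior × likelihood over a fixed grid (default 61
nodes on [−4.5, 4.5]).  The prior is truncated at the grid edges, so plain
equal-weight summation leaves an O(h) boundary error; Gregory
end-corrected weights (3/8, 7/6, 23/24) bring posterior means and SDs
within ~1e−5 of 10,001-point dense integration, verified against a
brute-force oracle in the tests.  MPWI selection maximises the item
information curve integrated against the current posterior; MFI (argmax at
the point estimate) is available, and ties break by bank order.  The first
item maximises information at the prior mean.  A test administers at least
one item and stops at SE < rule, pool exhaustion, or a length cap, in that
precedence.

Monte-Carlo studies draw θ ~ N(0,1) (or take an explicit list), generate
one full PCM response vector per iteration, and replay every stopping rule
on the same responses, so rules are compared on identical data.
Reliability is reported as 1 − (mean SE)²; the correlation column is
Pearson r between adaptive and full-bank EAP estimates.
Reliability-matched comparisons convert a published alpha to a stopping SE
via √(1 − α) rounded to two decimals (matching the precision at which such
rules are reported) and use the median test length, per the convention of
the tables they mirror.

## Synthetic data

The generator emulates a four-domain quality-of-life study: 320
respondents by default, domains of 28/24/12/32 five-category items,
θ ~ N(0,1), item locations uniform on [−2, 2].  Thresholds are evenly
spaced over ±`threshold_spread` with jitter of 0.2·spread, sorted and
centred; spread 0 degenerates to the rating-scale case.  Two spreads are
used deliberately:

- **1.5 logits** (default) for calibration-type fixtures: well-targeted
  Likert data in which every category is observed at N = 320.
- **3.0 logits** for the CAT-analogue bank: wide thresholds make single
  items carry ≈1 unit of information, so an 11-item bank attains
  individual-level reliability (.90) only with nearly the full test —
  matching the observed behaviour of real QoL item banks, where the
  SE < .32 rule consumes ~10 of 11 items.  This value was fixed by
  matching that test-length profile, not any downstream statistic.

Pathology injectors return ground-truth labels: a noisy duplicated column
(local dependency), a swapped-and-widened threshold pair (disordered
categories), a location shift for one factor level (uniform DIF,
default 0.5 logits), and a second orthogonal trait driving half the items
(multidimensionality).  Power of the corresponding screens at the sizes
used in the tests (n = 500–1000) is ≥80% per the seeded replicate suites.

What the synthetic design cannot show: real questionnaire data have
correlated item content, non-normal trait distributions, structured
missingness and cross-cultural DIF; passing these suites demonstrates the
machinery is correct and calibrated under the model, not that any
particular real instrument satisfies the model.

## Numerical and design choices

- Quadrature: 49 Gauss–Hermite nodes (calibration), 61-node uniform grid
  with Gregory end weights (CAT).  Dense-grid oracles guard both.
- Newton solves are damped (step clipped to 1 logit) and bounded to
  |θ| ≤ 10; degenerate Hessians fall back to scaled-gradient steps.
- Warm's correction uses the exponential-family form (Jeffreys-prior
  mode), so mirrored response patterns give mirrored estimates exactly.
- Class intervals, rest-score groups and grid sizes shrink automatically
  on small samples, with warnings rather than failures.
- Problem sizes in the test suites (320–2000 persons, 10–13 items,
  1000-replicate nulls, 10-replicate power runs) were chosen to keep the
  whole suite under a couple of minutes while leaving comfortable
  statistical margins.

## Known limitations

- The non-uniform DIF interaction test runs ~1 point above nominal size
  (see above); treat unadjusted interaction flags near α as advisory.
- Marginal ML with a fixed N(0,1) latent density differs from pairwise
  conditional estimation; absolute parameter values from other software
  will agree only up to the location/scale convention.
- EAP estimates are prior-shrunk; with very short tests the correlation
  against full-bank scores reflects shared shrinkage as well as shared
  information.
- No test equating, multidimensional IRT, content balancing or exposure
  control; one bank, one population, one latent dimension at a time.
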