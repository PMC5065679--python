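# catbank

Polytomous item-bank calibration and computer-adaptive testing (CAT)
simulation for patient-reported outcome measures such as quality-of-life
questionnaires.

Long Likert questionnaires are accurate but burdensome; clinicians and
trialists want the same measurement in a fraction of the items.  The route
is (1) calibrate the items as an *item bank* under the Partial Credit Model
(PCM), pruning items that violate its measurement assumptions, and
(2) administer the surviving items adaptively, choosing each next item to
be maximally informative about the respondent and stopping once a target
precision is reached.  `catbank` implements both halves plus the synthetic
data needed to exercise them, for psychometricians and health-outcomes
researchers.

## The model

The PCM (the polytomous Rasch model) gives a person at latent location
θ (logits) answering item *i* with categories 0…m a score *k* with

    P(X = k | θ) ∝ exp( D · Σ_{j≤k} (θ − δ_i − τ_ij) )

where δ_i is the item location, τ_ij are its category thresholds (centred
within item) and D is the logistic scaling constant (1.0 during
calibration, 1.7 inside the CAT engine to approximate the normal-ogive
metric).  Item information is D²·Var(X | θ) and adds across items.

**Calibration** is marginal maximum likelihood (EM over Gauss–Hermite
quadrature, standard-normal latent density) wrapped in an iterative
screening loop: a Mokken scalability screen (Loevinger H_i > .3) first,
then repeated PCM fits in which disordered category thresholds are repaired
by collapsing adjacent categories and the single worst item violating
local independence (residual r > .20), fit-residual bounds (±2.5),
chi-square item fit (P > .01) or DIF (ANOVA of residuals by person factor)
is removed, until every criterion passes.  A unidimensionality t-test
(split by the first principal component of the residual correlations) and
the Person Separation Index complete the audit.

**Adaptive testing** scores by expected a posteriori (EAP: posterior mean
over a 61-node grid, N(0,1) prior), selects items by maximum
posterior-weighted information (MPWI), and stops at a standard-error
ceiling; on the unit-variance metric reliability = 1 − SE².

## Worked example

```python
import numpy as np
from catbank import calibrate_item_bank
from catbank.calibration import CalibrationConfig
from catbank.cat import CatConfig, simulate_cat
from catbank.synthetic import (GeneratorSpec, generate_item_bank,
                               simulate_responses, inject_pathology)

# 320 respondents, 12 five-category items, plus one verbatim duplicate
bank = generate_item_bank(GeneratorSpec(seed=42), n_items=12)
thetas = np.random.default_rng(1).standard_normal(320)
responses = simulate_responses(bank, thetas, seed=2)
responses, _ = inject_pathology(responses, "dependency", {"noise": 0.0}, seed=3)

fitted, report = calibrate_item_bank(responses, CalibrationConfig())
```

The run prints an audit trail and a summary row:

```
status: criteria met
items retained: 12 of 13
  remove   item012      local_dependency
  rescore  item001      disordered_thresholds
total chi-square 34.1 (df 48, P = 0.94); PSI = 0.87; extremes 0.0%;
t tests significant 6.9%
```

The injected duplicate is caught by the residual-correlation screen and one
member of the pair removed; one item's estimated thresholds came out
disordered at this sample size and its categories were collapsed.  The
final bank fits (P = .94 well above the .01 floor), is reliable
(PSI .87) and well targeted (no floor/ceiling respondents).

Simulating adaptive tests on an 11-item bank wide enough that
individual-level reliability needs nearly every item:

```python
cat_bank = generate_item_bank(GeneratorSpec(seed=42, threshold_spread=3.0),
                              n_items=11)
summary = simulate_cat(cat_bank, None, CatConfig(stopping_se=0.32, seed=5),
                       n_iterations=1000, stopping_rules=[0.32, 0.45, 0.55])
print(summary.table)
```

```
             items_mean  items_sd  mean_se  reliability  correlation_with_full
stopping_se
0.32              10.80      0.40     0.32         0.89                   1.00
0.45               4.96      0.19     0.42         0.82                   0.96
0.55               3.00      0.05     0.51         0.74                   0.91
```

Reading the rows: stopping at SE < .55 (group-level reliability ≈ .70)
takes 3 items; SE < .45 (reliability ≈ .80) takes 5; individual-level
precision (SE < .32, reliability ≈ .90) uses nearly the full bank, and the
adaptive estimates are then indistinguishable from scoring every item
(r = 1.00).

The same pipeline is scriptable from a shell — `catbank generate`,
`catbank calibrate`, `catbank simulate`, `catbank compare`,
`catbank report` — using CSV responses, JSON banks and YAML configs; each
run writes a manifest with input digests and the seed.

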