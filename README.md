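# catlab

Polytomous-IRT item banking and computerized adaptive testing (CAT) for
Likert-type mental-health and behavioral instruments — built around the
workflow used to turn a pool of problematic-mobile-phone-use (PMPU)
questionnaires into an adaptive test: pool seven published scales into one
item bank, screen it, calibrate it, and then show that an adaptive test
drawn from the bank measures as accurately as the fixed scales with a
fraction of the items.

## Who this is for

Psychometricians and applied researchers who have (or can simulate) a
respondent × item matrix of ordinal responses and want to

- calibrate a **graded response model (GRM)** or **generalized partial
  credit model (GPCM)** item bank by marginal maximum likelihood,
- screen items for unidimensionality (PCA loadings, eigenvalue ratio,
  KMO), weak discrimination, and gender DIF (ordinal logistic regression,
  McFadden pseudo-R²),
- simulate post-hoc CAT on real or synthetic response data, and
- compare CAT against fixed short forms on accuracy, reliability and
  test length.

## The model

For an item with ordered categories t = 0, …, m−1, the GRM defines
cumulative probabilities

    P(X ≥ t | θ) = 1 / (1 + exp[−D·a·(θ − b_t)]),   t = 1, …, m−1

with discrimination a, ordered thresholds b_t and scaling constant D
(default 1.0), and category probabilities P(X = t) = P(X ≥ t) − P(X ≥ t+1).
The GPCM instead takes a softmax over cumulative step sums
Σ_{v≤t} D·a·(θ − δ_v). Trait scores are **EAP** (expected a posteriori)
posterior means under a standard-normal prior integrated on a fixed
quadrature grid. Measurement precision is Fisher information:

    SE(θ) = 1 / sqrt( Σ_i I_i(θ) ),    MR = 1 − (mean SE)²

where the sum runs over administered items and MR (marginal reliability)
summarizes a cohort. The adaptive loop starts at θ = 0, administers the
unanswered item with maximum information at the current estimate,
re-estimates θ, and stops at a target SE, a fixed length, or bank
exhaustion.

## Worked example

Simulate a 200-person cohort answering an 89-item synthetic GRM bank whose
discriminations (mean 1.26, range 0.87–2.36) and threshold span mirror a
pooled PMPU item bank, then replay each respondent through the adaptive
loop under three SE stop rules:

```python
from catlab import (SynthSpec, generate_bank, generate_thetas,
                    simulate_responses, StopRule, simulate_cohort, ItemBank)

spec = SynthSpec(seed=11)
bank = ItemBank(generate_bank(spec).items[:89], provenance="demo")
thetas = generate_thetas(200, spec, seed=21)
X = simulate_responses(bank, thetas, seed=22)

for target in (0.3, 0.4, 0.5):
    r = simulate_cohort(X, bank, StopRule.se(target))
    print(f"SE(theta) <= {target}: {r.mean_items:5.2f} items (SD {r.sd_items:.2f}), "
          f"mean SE {r.mean_se:.2f}, MR {r.mr:.2f}, r(full bank) {r.corr_with_full:.2f}")
```

prints

```
SE(theta) <= 0.3: 16.30 items (SD 0.91), mean SE 0.30, MR 0.91, r(full bank) 0.97
SE(theta) <= 0.4:  8.23 items (SD 0.51), mean SE 0.39, MR 0.85, r(full bank) 0.94
SE(theta) <= 0.5:  5.05 items (SD 0.23), mean SE 0.48, MR 0.77, r(full bank) 0.90
```

Read: stopping once SE(θ) ≤ 0.4 needs about 8 of 89 items per person, yet
the resulting trait estimates correlate 0.94 with estimates from the whole
bank and the cohort reliability is 0.85 — the core argument for adaptive
administration. Tightening the target buys reliability at the cost of
length.

The same steps are available from the shell:

```
catlab synth --seed 11 --bank-out bank.csv --responses-out X.csv
catlab calibrate --responses X.csv --model both --out est.csv --fit-report fit.json
catlab screen --responses X.csv --bank est.csv --report screening.json
catlab simulate-cat --responses X.csv --bank bank.csv --rule se:0.4 --out cat.csv
catlab evaluate --responses X.csv --bank bank.csv --out tables.csv
```

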