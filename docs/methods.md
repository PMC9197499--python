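# Methods

## Scope and latent-trait convention

`catlab` treats a pooled bank of ordinal (Likert) items as measuring one
latent trait θ on a standard-normal metric. Category codes are 0…m−1
internally; delimited-text I/O shifts 1-based Likert codes on read. The
logistic scaling constant D defaults to 1.0 (logistic metric) and can be
set to 1.7 where the normal-ogive metric is wanted; D multiplies a
everywhere, so the choice only rescales discriminations.

## Response models and information

The graded response model (GRM) defines P(X ≥ t|θ) as two-parameter
logistics with strictly ordered thresholds; category probabilities are
adjacent differences, and Fisher information uses the closed form
Σ_t (ΔP*′)²/P_t with P*′ = D·a·P*(1−P*). The generalized partial credit
model (GPCM) is a softmax over cumulative step sums with the δ₀ ≡ 0
convention and log-sum-exp normalization (stable for step arguments up to
about ±700); its information is D²a²·Var(T|θ). Both closed forms are
tested against central-difference numerical derivatives rather than
trusted as algebra. For m = 2 and equal parameters the two models
coincide, which the suite asserts to machine precision.

Precision is reported as the information-based standard error
SE(θ) = 1/√ΣI(θ̂) — the only SE formula consistent with the reliability
summaries the workflow produces (a description of SE as inversely
proportional to the *square* of test information is an erratum; the
reciprocal-square-root form is implemented). Cohort reliability is the
marginal reliability MR = 1 − (mean SE)².

## Calibration

Item parameters are estimated by Bock–Aitkin marginal maximum likelihood:
the trait is integrated over a fixed 61-node grid on [−4, 4] carrying a
standard-normal prior (this fixes the latent scale; no post-hoc
rescaling), the E-step computes posterior node weights per respondent, and
the M-step maximizes the expected complete-data log-likelihood item by
item with warm-started L-BFGS-B (inner iterations capped at 40 — a
generalized-EM step that still guarantees a nondecreasing observed-data
likelihood, which the tests assert at 1e−8 slack). GRM thresholds stay
ordered by construction: the optimizer works on (log a, b₁, log gaps).
EM stops when the likelihood improves by less than 1e−4 (default) or at
500 iterations; the convergence flag is honest. Items with fewer than two
observed responses or no variation are excluded and flagged; categories
never observed are collapsed with a warning and the item's m reduced
accordingly.

Model choice between GRM and GPCM uses AIC = −2LL + 2p and
BIC = −2LL + p·ln N with p = Σ_j m_j free parameters (one slope plus
m_j − 1 locations per item); AIC decides on disagreement, with a warning,
and exact ties default to the GRM. The −2LL of the original study's
calibration is not reproducible without its raw data; the package
reproduces the information-criterion arithmetic exactly and validates the
estimator by parameter recovery instead (below).

## Screening pipeline

Screening mirrors the item-banking order: first a principal-component
loading filter on the raw pool, then unidimensionality diagnostics on the
retained items, then (after calibration) a discrimination filter and a
DIF scan.

* **Loadings.** First-eigenvector components of the item Pearson
  correlation matrix scaled by √λ₁, majority-positive orientation;
  items with loading < 0.4 (strict) are dropped. Correlations are
  Pearson on raw integer codes with pairwise-complete observations —
  the common statistics-package default for this step; polychoric
  correlations are deliberately not implemented.
* **Unidimensionality.** λ₁/λ₂ > 4 and a first-factor variance share
  λ₁/p > 20% count as essentially unidimensional; the KMO statistic
  Σr²/(Σr² + Σq²) (anti-image partials from the inverse correlation
  matrix, ridge-regularized if singular) describes sampling adequacy.
* **Discrimination filter.** Calibrated items with a < 0.8 (strict) are
  dropped.
* **DIF.** Per item, proportional-odds logistic fits of response on the
  EAP trait anchor (M1) versus trait + group + trait×group (M3) —
  uniform and non-uniform DIF jointly; the effect size is the McFadden
  pseudo-R² difference with the intercept-only model as the null
  (its MLE reproduces the category proportions, so the null deviance is
  computed analytically). Items are flagged at ΔR² > 0.02 (strict). The
  trait anchor is the all-item EAP score, one pass, no purification.
  The fits are delegated to statsmodels' `OrderedModel` and were verified
  against an independent proportional-odds implementation to 7 decimals.

Two empirical properties of this DIF formulation are worth knowing. The
ΔR² produced by a fixed uniform threshold shift grows roughly with a²:
a +0.75 shift yields ΔR² ≈ 0.01 on an a ≈ 0.9 item but ≈ 0.03–0.05 on the
strongest items of a typical bank, so weakly discriminating items need
larger shifts (or samples) to cross the 0.02 flag. And when the studied
item dominates a short anchor, part of the shift is absorbed into the
anchor itself; power tests therefore use a 20-item bank. Under those
conditions the suite measures 10/10 sensitivity at n = 2000 and a 0/190
false-flag count under the null.

## Adaptive testing

Post-hoc simulation replays a respondent's recorded answers as if
administered adaptively: start at θ = 0 (the prior mean), select the
unanswered item with maximum Fisher information at the current estimate
(ties to the lowest bank position), read the recorded answer, update the
posterior, and re-estimate. At least one item is administered before any
stop check; SE after zero items is infinite. Stop rules: target SE
(stop at the first count where SE ≤ target, else bank exhaustion), fixed
length, or "all". A missing recorded answer makes that item unavailable
for that respondent — selection recomputes rather than imputes. The loop
is fully deterministic; per-person posteriors are updated incrementally
and item informations cached per θ value.

EAP integrates the same 61-node grid used in calibration, with Simpson
coefficients folded into the prior weights so grid sums are O(h⁴)
quadrature; against a 10,001-point trapezoid oracle the worst observed
error is below 1e−6, comfortably inside the 1e−4 contract asserted in the
tests. The SE used for stopping and reporting is the information-based
SE at the current EAP estimate — the same quantity the reliability
summaries use; the posterior SD is returned alongside for comparison.

Cohort simulation aggregates per-person runs into mean/SD items used,
cohort mean SE, MR, and the Pearson correlation of trait estimates with
the full-bank ("all") EAP baseline.

## Evaluation against fixed forms

Fixed scales are scored by EAP on their items only, under the joint
calibration (a single latent metric keeps cross-arm correlations
meaningful — per-scale recalibration would put each scale on its own
scale). Equal-length contrasts pair each fixed scale with a fixed-length
CAT of the same length; reported statistics are per-arm mean (SD) of
per-person SEs, MR, percent change relative to the fixed arm, the paired
t statistic, and Cohen's d = t/√n — the standardized paired mean
difference, which is the convention that reproduces published effect
sizes of this design. Percent changes are reported to one decimal and
SE/MR to two, matching standard reporting. Equal-accuracy comparisons
feed each fixed scale's achieved mean SE back in as a CAT stop target and
report the mean adaptive length; respondents who exhaust the bank before
reaching the target are counted and reported, not silently dropped.

## Synthetic data generator

The generator emulates the pooled seven-scale PMPU item pool: scales of
16×7, 10×4, 20×4, 11×5, 16×5, 11×5 and 14×5 items×categories (98 items),
discriminations from a truncated normal with mean 1.26 and SD 0.31 on
[0.87, 2.36], thresholds drawn uniformly on [−2.4, 3.6], sorted, with a
minimum gap of 0.2 to avoid near-degenerate categories, and θ ~ N(0, 1).
Responses are drawn from the exact model category probabilities (verified
by χ² goodness of fit). Optional plans plant uniform/non-uniform DIF
(threshold shift and/or slope multiplier for a group-B bank copy) and
weak items (a ≈ 0.05–0.15) as ground truth for the screening filters.
All randomness flows through one seeded generator per call.

What the generator does **not** emulate: local dependence between items
of the same scale (symptom overlap), response styles (acquiescence,
careless responding), missingness mechanisms, and any multidimensional
structure. Passing tests therefore demonstrate that the algorithms behave
correctly under clean unidimensional conditions, not that a real pooled
questionnaire bank satisfies those conditions.

## Problem sizes used by the test suite

The suite favors sizes that make the statistical assertions stable:
parameter recovery pools five replicate 10-item banks at n = 1000 (a
single replicate's threshold RMSE is dominated by the handful of
responses behind each extreme threshold and swings by ±0.05 across
seeds); DIF power uses ten 2000-person two-group cohorts; cohort
stop-rule gradients use 200 respondents on an 89-item bank. Weak-item
loading tests allow up to two borderline genuine casualties per run —
items with a near the 0.87 envelope floor and skewed thresholds
legitimately graze the 0.4 Pearson-loading cut from above.

## Known limitations

- Single latent dimension only; no testlet, nominal or multidimensional
  models.
- No item-parameter standard errors and no propagation of calibration
  uncertainty into CAT scoring (trait estimation treats item parameters
  as fixed).
- No exposure control or content balancing in item selection.
- DIF scanning covers one binary grouping at a time, lordif-style
  ordinal logistic only (no Mantel–Haenszel or IRT likelihood-ratio
  variants), without purification iterations.
- Screening correlations are Pearson on integer codes; with few
  categories and skewed thresholds they understate latent correlations,
  which is visible in the loading filter's borderline behavior.
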