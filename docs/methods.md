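# Methods

## Data model

The analysis substrate is a wide table: one row per child, a module-algorithm
label (1.1, 1.2, 2.1, 2.2, 3), grouping variables (race, sex, optional
ethnicity flag) and 14 harmonized item scores — 10 social-affect (SA) and 4
restricted/repetitive-behavior (RRB) items. Raw scores live in
{0, 1, 2, 3} plus the special codes 7 ("other abnormality") and 8 ("not
applicable"). Before modeling, scores of 3 are collapsed to 2 (aligning with
algorithm scoring) and the special codes map to 0. The 7/8 → 0 mapping is a
scoring convention, not an empirical fact, so it is a configurable
`RecodeRules` entry. Recoding is idempotent; after it, every item is
3-category except *gaze* in algorithm 1.1, which is dichotomous. Modeling
uses complete cases only: rows with any missing item response or missing
race/sex/algorithm label are dropped (a blank ethnicity field is a legal
"not reported" state and never drops a row). For the racial comparison,
Hispanic-flagged rows are removed first; the flag is ignored for the sex
comparison. Group labels match case-insensitively after trimming, and the
reference group is the majority group (White, male) by convention. Duplicate
person identifiers within one algorithm are fatal, since the design assumes
one assessment per child per algorithm.

## Graded response model

P(X ≥ k | θ) = logistic(a(θ − b_k)) with a > 0 and strictly increasing
thresholds. No 1.7 scaling constant: the logistic metric is used as-is,
matching current IRT software practice. Category probabilities are adjacent
differences of the cumulative curves; the expected item score is
Σ_k P(X ≥ k | θ); the expected test score is the sum over items (maximum 27
for the 1.1 algorithm with its dichotomous gaze item, 28 otherwise).

**Calibration.** Marginal maximum likelihood with the latent trait
integrated over 49 equally spaced quadrature nodes on [−6, 6], weighted by a
renormalized N(0, 1) density (node count and bounds configurable). The EM
loop computes posterior node weights per person (E-step) and updates each
item by a batched Newton ascent on the expected complete-data
log-likelihood (M-step): analytic gradient, finite-difference Hessian,
eigenvalue-shifted to negative definite, with per-item step-halving so the
objective never decreases. Convergence is declared when the largest absolute
parameter change falls below 1e−4 (at most 500 cycles); the marginal
log-likelihood trace is retained and is non-decreasing by construction.
Starting values: a = 1, thresholds from logits of pooled cumulative category
proportions. Items with fewer than two observed categories are excluded with
a warning; an unobserved intermediate category is collapsed for that
calibration and recorded. Standard errors come from the cross-product
(empirical Fisher) approximation to the observed information.

**Identification.** Single-group fits fix θ ~ N(0, 1). Multi-group fits fix
the reference group at N(0, 1), constrain anchor items equal across groups,
free the studied items (fully, or thresholds-only for the intermediate
IRT-LR model), and estimate the focal latent mean and SD from posterior
moments each cycle. At least one anchor is required; an all-free model is
rejected as unidentified. EAP scores are posterior means under the fitted
parameters and the N(0, 1) prior, so they always lie inside the node range.

## DIF detection and effect sizes

Two engines are provided because the field uses both and they answer the
same question through different likelihoods:

1. **Ordinal-regression nested models** (default, and the source of the
   magnitude statistics). Per item, proportional-odds fits of
   `item ~ θ`, `item ~ θ + group`, `item ~ θ + group + θ×group` on the EAP
   score (statsmodels `OrderedModel`; larger models warm-started from
   smaller ones so the nesting inequality holds numerically). LR χ²
   contrasts: M2 vs M1 (uniform, df 1), M3 vs M2 (nonuniform, df 1),
   M3 vs M1 (total, df 2); the total decomposes exactly into the two parts.
2. **Anchored IRT-LR tests.** Multi-group GRM fits on the anchors plus the
   studied item: all-equal vs thresholds-free vs fully free; χ² = 2·Δll with
   df = number of freed parameters. The pipeline can run either or both and
   logs engine disagreements.

Magnitude grading: McFadden pseudo-R² differences between nested models
(ΔR² ≥ 0.02 meaningful); ∆β = 100·|β_θ(M2) − β_θ(M1)|/|β_θ(M1)| (≥ 10%
meaningful), defined on the θ coefficient because that is the established
form of the coefficient-change criterion; a ~zero M1 coefficient makes ∆β
undefined (flagged, never silently 0). Classification: a significant
interaction wins (nonuniform), else a significant group term (uniform),
else none — interaction presence invalidates a pure threshold-shift
description. No multiple-testing correction by default (two-sided α = 0.05);
a Bonferroni-style option can be expressed by lowering α in the config.

**ESSD** (item level): mean over focal persons of reference-minus-focal
expected item scores, divided by the pooled SD — the root mean of the two
ddof=1 variances of the expected-score vectors. Positive ESSD ⇒ the item is
harder for the focal group ⇒ severity underestimated at equal θ. **DTF**
(scale level): per focal person, expected total score under reference minus
under focal parameters; ETSDS = signed mean, UETSDS = mean of absolute
values (raw scale points; an RMS variant would be a one-line change and is
deliberately not the default), ETSSD = ETSDS / pooled SD of the two
expected-total-score vectors. UETSDS ≥ |ETSDS| always. Anchored items
contribute zero difference, so a single biased item is diluted in ETSSD
relative to its own ESSD.

**Anchor purification** (optional): iteratively calibrate on the current
anchors, EAP-score, test all items, and drop from the anchor set items that
are both significant and pass the ΔR² ≥ 0.02 screen; stop at a fixed point
or 10 rounds, never emptying the set.

## Dimensionality

Polychoric correlations use two-step ML (thresholds from margins, ρ by
bounded likelihood maximization over the contingency table; boundary
estimates clamped to ±0.999 and flagged). The unidimensional model is the
GRM itself; the confirmatory two-factor model puts SA items on one factor
and RRB items on the other, correlated standard-normal factors, fitted by
full-information EM on a 21 × 21 product grid over [−5, 5]² with ρ updated
from posterior cross-moments (clamped to ±0.95; on truly unidimensional
data ρ runs to the clamp, which is itself diagnostic).

Fit diagnostics are limited-information statistics on first- and
second-order margins: X² = n Σ (p_obs − p_model)²/p_model over univariate
category cells and bivariate contingency cells; df = non-redundant margin
statistics minus free parameters; CFI/TLI against an independence baseline
on the same margins; RMSEA = √(max(X² − df, 0)/(df·n)); SRMR = RMS of raw
bivariate probability residuals (probability-scale residuals are used
instead of residual polychorics because re-estimating 91 polychoric
correlations per fitted model is needlessly expensive and changes no
qualitative conclusion). These are comparative diagnostics, not calibrated
χ² tests. The *preference* between structures minimizes a BIC-style
penalized discrepancy, X² + ln(n)·(#parameters): because the two-factor
model nests the unidimensional one (ρ → 1), an unpenalized discrepancy
ratio decides by noise on unidimensional data, while measured gaps are ≤ ~4
under one-factor truth versus ~100+ under two-factor truth at n = 400, so a
ln(n)-per-parameter price separates the regimes cleanly.

## Synthetic data

The generator emulates the study conditions the analysis assumes: five
module-algorithms with the 10 + 4 item layout; two groups with unbalanced
clinic-like sizes (e.g. module 3: 1782 vs 660 for the racial comparison,
2394 vs 612 for sex; the other algorithm cells likewise); reference latent
trait fixed at N(0, 1) with configurable focal impact (mean/SD); true item
parameters drawn once per design from a ∈ [0.5, 3.5], b₁ ∈ [−2, 1.5] with
gaps in [0.5, 1.5] (so b₂ ≤ 3), then frozen so generating truth is always
available; uniform DIF planted as an additive focal-threshold shift and
nonuniform DIF as a multiplicative discrimination factor. Impact defaults to
none — it is a free simulation knob, not an estimate of any population.
Everything is deterministic under a fixed seed.

What the generator does *not* emulate: clinical referral bias, rater
effects, item-level local dependence, missing-data mechanisms beyond MCAR in
tests, and calibrated-severity-score distributions. Passing tests therefore
demonstrate the statistical machinery's correctness and operating
characteristics under the stated generating model, not properties of any
clinical sample.

## Simulation studies and problem sizes

`studies.py` holds the Monte-Carlo experiments; each replicate runs the same
code path as the pipeline. Conditions: type-I error and null effect-size
calibration use 200 replicates of n = 500/group, 14 items, a ∈ [1, 2.5], no
DIF; power and direction use 200 replicates with a uniform threshold shift
of 0.6 on one RRB item; dimensionality recovery uses 50 replicates of
n = 400 per structure with factor correlation 0.5; parameter recovery uses
one n = 3000, 14-item calibration. `scripts/acceptance.py` reports the same
quantities at 80/80/20 replicates, its per-key `n` recording the size used.
Observed behavior (recomputed by the tests and the script, not asserted
here beyond their own tolerances): null rejection near α, power near 1 at
shift 0.6, null effect sizes near zero, both structures recovered.

## Numerical choices and edge cases

Probability floors at 1e−12 guard logs; quadrature weights must be positive
and sum to 1; LR statistics below −1e−6 are treated as optimizer failures
(fatal), small negatives are clipped to 0. Degenerate items (constant in the
analysis sample) are excluded with a warning; separation or non-convergence
in the ordinal regressions yields a flagged, excluded item rather than a
silent number. Report tables are rendered with a fixed float format so
identical configurations are byte-identical. Seeds for pipeline cells and
replicates derive from `numpy.random.SeedSequence` spawns of the single
user-facing seed.

## Known limitations

- The EM engine targets the 2- and 3-category items of this instrument;
  it accepts more categories but is untuned for them.
- The two detection engines need not agree on borderline items; the
  pipeline reports ordinal-regression results as primary and logs
  disagreements rather than adjudicating.
- Limited-information fit indices use a Pearson-type moment statistic, not
  the weight-matrix-corrected forms; they are intended for the one- vs
  two-factor comparison, not absolute-fit hypothesis testing.
- DTF aggregation assumes the focal-sample EAP distribution is an adequate
  stand-in for the focal severity distribution; heavy shrinkage at extreme
  severities compresses expected-score differences slightly (visible as
  planted shifts recovering at ~80–90% of their nominal size).
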