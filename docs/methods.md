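# Methods

## The rurality scale

De-identified health datasets typically release geography only as the
first three digits of the participant's ZIP code, with low-population
areas recoded to `000` (the HIPAA safe-harbor rule). Three-digit areas
are too coarse for the usual rural taxonomies (RUCA, IRR, county-based
measures), which is the gap this package fills: a continuous score per
3-digit prefix computed from public 5-digit inputs.

Given a national table of 5-digit ZIP codes with populations and a list
of ZIP codes designated rural by the federal rural-health grant
eligibility criteria, every ZIP is tagged rural or non-rural, grouped by
its first three digits, and each prefix *g* scored

```
percent_rural(g) = 100 * rural_population(g) / total_population(g)
```

where both populations are exact integer sums over the prefix's ZIPs.
The score is a population-weighted rural share in [0, 100];
`100 − percent_rural` is by construction a percent-urban score. Scores
are held at full float precision internally and rounded only for
presentation.

Edge handling:

* **Zero-population prefixes** have an undefined (0/0) score and are
  reported as NaN; participants mapping there are excluded with a logged
  reason rather than assigned an arbitrary endpoint.
* **Prefix `000`** is the safe-harbor suppression code, not a place;
  participants carrying it are always excluded (`suppressed_prefix`).
* **Endpoint strata** (fully urban = exactly 0%, fully rural = exactly
  100%) are set-membership facts — a prefix is fully rural iff
  `rural_population == total_population` as integers — so exact equality
  comparison is safe: 0 and 100 arise from ratios 0/n and n/n, both
  exact in floating point.
* **Rural-list entries absent from the population table** are counted
  and logged but create no records: with zero population they cannot
  move any weighted score.
* **Duplicate ZIPs in the population table are an error**, not silently
  summed, because silent summation can hide a mix of crosswalk vintages.
* No intermediate urban/suburban/rural cut-points are defined; the scale
  is continuous and thresholds along it are left to future work.

## Composite outcomes

Two binary outcomes are coded from a healthcare access & utilization
survey: **delayed care** from 9 designated items with threshold 6, and
**healthcare affordability** from 14 items with threshold 9 (a
participant is coded 1 iff at least the threshold number of items are
answered affirmatively). The thresholds are deliberately conservative,
flagging persistent or widespread barriers rather than isolated ones.

Which items constitute each domain is configuration (a YAML manifest
validated for cardinality 9/14), since instruments differ; per-item
affirmative value sets accommodate reverse-worded items. Missing,
skipped, and refused responses count as non-affirmative — conservative
toward coding 0 and well-defined for partial responders — and
`min_answered` (default 1) lets an analysis require a minimum number of
answered items before a participant is assessed at all. Coding is a pure
function of (responses, manifest, min_answered); monotone in affirmative
answers; and flips 0→1 exactly at the threshold.

## Distribution comparison

Rurality scores are heavily tied (all participants in a prefix share one
value) and far from normal (a large mass at exactly 0), so group
comparison is fully non-parametric:

* **ECDFs** of the score are built per outcome group as right-continuous
  step functions with duplicate values merged; the terminal height is
  pinned to exactly 1.
* The **two-sample Kolmogorov–Smirnov statistic** is the supremum gap
  `D = sup_x |F1(x) − F0(x)|` evaluated at *every pooled observed value*,
  which is exact in the presence of ties.
* The **p-value** uses the asymptotic Kolmogorov tail
  `Q(λ) = 2 Σ_{k≥1} (−1)^{k−1} exp(−2k²λ²)` with the standard
  effective-sample-size correction `λ = (√nₑ + 0.12 + 0.11/√nₑ)·D`,
  `nₑ = n₁n₂/(n₁+n₂)`. The series is truncated when terms fall below
  1e-12 and the result clipped to (0, 1]; for λ < 0.2 the tail equals 1
  to well within that tolerance, and is returned as 1 directly because
  the alternating series converges slowly there. At cohort scale the
  asymptotic form is the operative one; small-sample agreement is
  checked in tests against an independent implementation of the series
  and against a general statistics library. Only the two-sided test is
  provided.

## Stratified descriptive tables

For each endpoint stratum, counts and percentages per sociodemographic
category (race, ethnicity, sex at birth, education) and age mean/SD are
reported. The percentage denominator is the number of stratum members
who provided *any* demographic information; within-category missing
values form a "Missing" level so counts sum to the denominator.
Percentages are rounded **half-up** — one decimal within tables, whole
percent for enrollment shares — because that convention reproduces
standard printed enrollment tables where banker's rounding would not.

## The synthetic cohort

The participant-level data this pipeline targets is access-restricted,
so a generator produces structurally faithful stand-ins for all four
inputs from a single integer seed (one `numpy.random.Generator` stream;
the cohort stage derives its stream from `seed + 1` so universe and
cohort draws are independent but jointly reproducible; fixed seed ⇒
byte-identical files).

Defaults, chosen once as a realistic desk-scale world:

| parameter | default | meaning |
|---|---|---|
| `n_prefixes` | 200 | 3-digit areas (of ≤999 possible; `000` reserved) |
| `zips_per_prefix` | 5–30 | uniform count of 5-digit ZIPs per prefix |
| `population_median`, `population_sigma` | 8,000, 1.0 | log-normal ZIP population (persons) |
| `rural_beta_a`, `rural_beta_b` | 0.4, 0.6 | Beta prefix rural propensity (U-shaped, rural-leaning tails) |
| `frac_forced_urban`, `frac_forced_rural` | 10%, 5% | point masses at propensity exactly 0 / 1 |
| `n_participants` | 20,000 | cohort size |
| `effect_beta` | 1.0 | log-odds of an affirmative item answer per unit rurality fraction |
| `intercept_delayed`, `intercept_affordability` | −1.2, −1.0 | per-item baseline log-odds at 0% rural |
| `no_demographics_rate` | 1.5% | participants providing no sociodemographics |

Each prefix draws a rural propensity and flags its ZIPs rural
independently with it; the forced point masses guarantee non-empty
fully-urban and fully-rural strata at desk scale. Participants land in
prefixes with probability proportional to prefix population, and each of
the 9 + 14 items is answered "Yes" with probability
`logistic(α_item + effect_beta · r)`, `r = percent_rural / 100`. The
logistic-in-rurality form is the minimal monotone mechanism that yields
the ECDF separation the analysis is designed to detect, with `beta = 0`
an exact null; demographic level frequencies loosely follow a large US
research cohort's overall composition, with an optional rurality tilt
per category.

What the generator does **not** emulate: real enrollment geography and
prefix populations, item-level dependence beyond the shared rurality
slope, differential non-response, or the demographic margins of any
actual cohort. Passing tests therefore certify the computations (scores,
coding, ECDF/KS, tables) and the qualitative rural-disparity direction
under a known mechanism — not any quantitative claim about real data.

## Problem sizes and numerical checks

The shipped analysis and the reproduction script use 200 prefixes and
20,000 participants — large enough that the headline KS comparison is
overwhelmingly significant (p at the 1e-12 reporting floor) while the
whole pipeline runs in seconds. Test-suite checks use: brute-force
oracle agreement for the scale (≤20 ZIPs, 1e-12 relative) and for the KS
statistic (1,000 tied pairs of size ≤50, exact equality); asymptotic
p-value agreement with an independent series implementation to 1e-6;
type-I error of the KS test on population-weighted tied score draws
(500 replicates of 500 vs 500) within [0.03, 0.07] at α = 0.05; and
exact population conservation plus strict monotone response of the scale
on 100 random universes.

## Known limitations

* Three-digit areas mask local heterogeneity; a participant's score is
  the area's rural share, not a personal exposure measure.
* The asymptotic KS p-value is conservative under heavy ties; at desk
  scale and cohort scale this does not change conclusions, but exact
  small-sample p-values are out of scope.
* No covariate adjustment, regression modeling, or multiple-testing
  correction; the comparison is a single two-sided test per outcome.
* No ZIP↔ZCTA crosswalking: inputs are taken as ZIP-keyed tables, and
  version/vintage metadata of those inputs is recorded but not
  validated.
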