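# Methods

This note documents the models, conventions and numerical choices behind
`btmbkit`, and what the synthetic-data checks do and do not establish.

## Burden scoring

**Score definition.** For one plasma sample, the bTMB score is the number
of distinct `(position, ref, alt)` single-nucleotide substitutions over the
panel footprint that are (a) classified somatic, (b) at allele frequency
≥ `af_min` (default 0.005, the assay's validated lower bound for
substitutions), and (c) not flagged as known drivers. Insertions and
deletions never count. Multiple substitutions at one position count
separately because the key includes the alleles; this convention is a
package choice and is exercised by the tests. Germline filtering runs
before the AF threshold is applied. The score divided by the panel's
coding footprint (default 1.1 Mb) gives mutations per megabase, so 16
counted substitutions ≈ 14.5 mut/Mb.

**MSAF and evaluability.** MSAF is the maximum allele fraction over
somatic substitutions strictly below 0.20 (fractions at or above 20% are
treated as likely germline/clonal-hematopoiesis signal and never set the
tumor-content estimate); driver status does not exclude a call from MSAF.
Samples with MSAF < 0.01 are non-evaluable: the score is computed but
masked (`None`), and such samples form their own `non_evaluable` group in
every downstream comparison.

**Germline surrogate.** Production assays classify variant origin with a
read-level somatic–germline–zygosity model that needs depth and
copy-number input this package does not handle. The package instead uses
an explicit surrogate: a call is germline if it appears in a population
database (dbSNP/ExAC-style membership, carried as a flag or matched
against the panel's SNP key set) **or** its allele fraction lies within a
band (default ± 0.05) of the heterozygous (0.5) or homozygous (1.0)
fraction. The band is configurable; the rule is deliberately simple,
fully testable, and stated wherever results depend on it. Somatic
fractions in cfDNA rarely approach 0.45, so at default settings the band
essentially never misclassifies true somatic calls; it does misclassify
germline variants whose observed fraction drifts outside the band, which
a read-level classifier would catch.

## Efficacy statistics

All estimators are implemented from first principles (scipy provides only
distribution functions); `lifelines` and `statsmodels` appear in the test
suite as independent cross-checks, never in the implementation of these
primitives.

- **Blaker exact interval.** The interval is the hull of parameter values
  whose two-sided acceptability (the smaller tail probability plus the
  largest opposite-tail probability not exceeding it) is at least
  1 − conf. Endpoints are found by scanning inward from the
  Clopper–Pearson bounds (which provably contain the Blaker interval) on
  a 400-point grid and bisecting the crossing to 1e-8. By construction
  the result is nested in Clopper–Pearson and contains x/n.
- **CMH test.** With one stratum this is the Mantel–Haenszel chi-square
  — the Pearson statistic scaled by (N−1)/N — without continuity
  correction; strata are pooled by summing hypergeometric means and
  variances. One degree of freedom, two-sided p.
- **Rate difference.** Unpooled Wald normal interval, reported in
  percentage points. The method is not dictated by the reporting
  convention being reproduced; the unpooled Wald form was chosen because
  it reproduces the published 90% intervals from the reconstructed
  counts, and that reproduction is frozen in the tests.
- **Odds ratio.** (a·d)/(b·c) with the Woolf logit interval, chosen on
  the same grounds. A zero cell triggers the Haldane–Anscombe 0.5
  correction, flagged in the result.
- **Kaplan–Meier.** Product-limit over distinct event times; censored
  observations at an event time remain at risk for the events at that
  time. The Greenwood variance is accumulated on the plain survival
  scale. With case weights (used by IPW), risk sets and event counts are
  weighted sums and the Greenwood accumulation uses the weighted counts —
  exact in the unweighted case, a standard approximation otherwise.
- **Median interval (Brookmeyer–Crowley).** The median is the first event
  time with S(t) ≤ 0.5. The interval inverts
  (S(t) − 0.5)² / Var[S(t)] ≤ χ²₁(conf) over event times: the lower bound
  is the first qualifying event time; the upper bound is the first event
  time after the qualifying run (beyond follow-up ⇒ not estimable,
  reported as `None`). The inversion uses the plain-scale Greenwood
  variance; `lifelines` inverts a log(−log) band instead, so the two
  agree on the median and usually — not always — on the bounds. Simulated
  coverage at n = 200 exponential cohorts is ≈ 94–95% at the 95% level
  (checked in the acceptance suite).
- **Landmark survival.** Normal interval for S(t\*) on the plain scale
  (clipped to [0, 1]) by default, matching the Greenwood-formula wording
  of the reporting convention; a complementary log-log transform is
  available by flag and is preferable near the boundaries.
- **Log-rank.** Unweighted, pooled over distinct event times, with the
  hypergeometric variance; two-sided p from χ²₁. Its permutation law is
  verified against an enumeration oracle on small fixtures.
- **Cox hazard ratio.** Single binary covariate, partial likelihood
  maximized by damped Newton iteration (steps clipped to ±2, tolerance
  1e-10, max 60 iterations), Efron tie handling by default with Breslow
  by flag; weighted fits use the Breslow form, the convention for
  IPW-weighted hazard models. Hazard ratios are oriented
  high-versus-low — HR < 1 favors the high-burden group — and intervals
  are Wald on the log scale at a caller-chosen level (trial convention
  90%). A group with no events yields a monotone likelihood; the fit is
  flagged and the interval reported unbounded rather than a spurious
  number.
- **Power.** Schoenfeld's approximation: with d expected events and
  high-prevalence p, power = Φ(√(d·p·(1−p))·|log HR| − z₁₋α/₂). The
  default event fraction 0.87 makes the published design point (80%
  power for HR 0.6 at n = 150, two-sided α = 0.10) come out at 80%.

## Cutoff sweep

One row per cutoff in {10, 12, …, 20}: group sizes, per-group ORR with
Blaker intervals, PFS/OS Cox hazard ratios with 90% intervals, log-rank
p-values and Brookmeyer–Crowley medians, all computed by the same
primitives. Non-evaluable patients are excluded from every row; a cutoff
that empties a group is flagged not estimable. Group membership is nested
across cutoffs by construction.

## IPW analysis of the MSAF subgroups

Baseline factors (age, tumor size as sum of longest diameters, target
lesion count; smoking, PD-L1 status with an explicit `missing` level,
histology, sex) are screened between the MSAF < 1% and ≥ 1% groups at
p < 0.15 — Wilcoxon rank-sum for continuous factors; categorical factors
are screened level by level as binary indicators (current smoker, PD-L1
positive, ...) by chi-square without continuity correction, Fisher exact
for sparse tables, keeping the strongest level per factor. The screening
tests are a package choice; the reporting convention names only the
p < 0.15 rule and screens level indicators. Screened factors enter a
logistic propensity model for MSAF < 1% membership, fitted by IRLS
(statsmodels GLM). Separation — diverging coefficient or fitted
probability at 0/1 — raises an error advising factor removal; the
full-chain driver responds by dropping the screened factor with the
weakest evidence and refitting.

Weights are the unstabilized inverse probabilities (1/p and 1/(1−p)),
truncated at the 1st/99th weight percentiles **within each MSAF group**
(count reported); stabilized weights are available by flag. Truncating on
the pooled weight distribution would clip exactly the most informative
low-propensity patients — the two groups' weight scales differ by an
order of magnitude — and demonstrably biases the adjusted estimate, so
the per-group convention is the default. The adjusted odds-ratio interval uses a
linearized (Horvitz–Thompson/sandwich-style) variance of the weighted
log-odds in each group; its near-nominal coverage is established in the
confounding simulation rather than assumed. Weighted PFS uses the
weighted Kaplan–Meier median (same inversion as above, on the weighted
curve) and the weighted Breslow–Cox hazard ratio. Balance is summarized
by standardized mean differences per screened factor (largest per-level
difference for categorical factors), with the pooled unweighted SD as the
common scale before and after weighting.

## Gene-level prevalence

A sample's gene is "altered" if the sample carries at least one SNV or
indel call — germline and driver filtering are deliberately **not**
applied here, matching the exploratory molecularly-evaluable-population
convention, and no gene-size normalization is performed. Genes at ≥ 2%
prevalence in the MEP (non-evaluable samples count in this denominator)
are tested high vs low by two-sided Fisher exact and adjusted by
Benjamini–Hochberg (statsmodels; verified in the tests against a direct
step-up enumeration, with Fisher verified against hypergeometric
enumeration).

## Synthetic cohort generator

The generator's defaults are the study conditions, fixed once:

- **Cohort**: 152 patients; evaluability (MSAF ≥ 1%) Bernoulli(0.78);
  evaluable MSAF log-normal (log-mean −3.2, log-sd 0.8) clipped to
  [0.01, 0.199]; non-evaluable MSAF uniform below 1% with a 15% chance of
  no ctDNA at all.
- **Scores**: round(log-normal) with log-sd 0.9 and log-mean set by
  quantile matching so P(score ≥ 16) = 0.24 among evaluable samples
  (matching at 15.5 to account for rounding). The true score histogram is
  unpublished; only the two printed fractions anchor the calibration.
- **Response**: Bernoulli by group — 35.7% (high), 5.5% (low), 37.9%
  (non-evaluable), the published rates.
- **Survival**: exponential by default (Weibull shape by flag) for
  analytic tractability of recovery tests. PFS: low-group median 3.5
  months, hazard ratio 0.80 for high and 0.62 for non-evaluable; OS:
  low-group median 13.4 months, ratios 0.66 and 0.80. An alternative
  score-level mode makes the PFS log-hazard linear in the score (used
  with slope −0.06 per score unit for the cutoff-trend simulation).
  Censoring: uniform 18-month accrual with a data cut at 36.5 months,
  plus a small dropout hazard (0.005/month).
- **Covariates**: imbalances between MSAF groups at the published
  magnitudes (age means 65 vs 70; current smoking 14% vs 25%; PD-L1
  positive 52% vs 38% with 36% missing overall; mean lesions 1.8 vs 2.4;
  SLD medians 42.4 vs 70.0 mm); squamous histology tied to the burden
  group (46% high vs 24% low).
- **Variant profiles**: per evaluable patient, one somatic anchor SNV at
  exactly the patient's MSAF and score−1 passengers uniform in
  [0.005, MSAF]; a known driver with probability 0.5 (counted for MSAF,
  excluded from the score); Poisson indels at 10% of the somatic count;
  ~Poisson(30) germline variants at fractions near 0.5 or 1.0, 90%
  database-flagged (the remainder is caught by the band rule). The
  germline count is a down-scaled representative background chosen to
  keep whole-cohort replication cheap; a real 1.1 Mb panel carries
  hundreds of common germline variants per sample, which would change
  nothing in the logic. Gene-level enrichment is planted by relabelling
  passenger genes (TP53 0.80 vs 0.40 high/low, LRP1B 0.45 vs 0.25,
  CDKN2A 0.30 vs 0.15).
- **Confounded-MSAF mode**: a prognostic index (younger age, smaller SLD,
  fewer lesions, non-smoking, PD-L1 positivity) drives both MSAF < 1%
  membership (logit intercept at 13% prevalence, slope 2.2) and response
  (logit intercept at 15%, slope 2.0) and scales the PFS/OS hazards;
  MSAF itself has no effect. The slopes were calibrated so the marginal
  unadjusted odds ratio ≈ 3–4 and the group response rates ≈ 38% vs 16%,
  the published order of the apparent MSAF effect. Setting
  `confounding_strength = 0` removes all signal.

Determinism: one `numpy` Generator seeds everything; identical config and
seed give byte-identical output files.

**What passing checks show — and don't.** The generator plants exactly
the structures the analysis is meant to recover (exponential hazards,
logistic response, log-normal scores, correctly specified confounders).
Passing recovery and coverage checks therefore establishes the
correctness of the estimators and the internal consistency of the chain,
not performance on real trials, where hazards are non-proportional,
missingness is informative, confounding is partly unmeasured, and variant
profiles include artifacts the surrogate germline rule cannot see.
Patient-level survival results of the original trial (medians, hazard
ratios) are access-controlled and are deliberately not targeted.

## Problem sizes of the reproduction script

`scripts/acceptance.py` uses: 200 random fixtures (n ≤ 30) for the
Kaplan–Meier oracle; 500 replicates at 150/arm for Cox recovery of HR
0.6; 1,000 exponential cohorts of 200 for median/landmark coverage; the
full x ≤ n ≤ 60 grid for Blaker nesting; 500 confounded cohorts of 152
for IPW; 200 cohorts for the cutoff trend; 1,000 random fixtures and 500
simulated cohorts for scoring and calibration. These sizes were chosen so
Monte-Carlo error is comfortably inside the stated tolerances while the
whole script stays in the minutes range on one CPU.
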