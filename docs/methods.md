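# Methods

## Problem and scope

`pvsignal` mines spontaneous-reporting-system (SRS) data for drug–event
signals. The reference use case is a cross-national safety profile of the
topoisomerase-I inhibitor irinotecan built from two SRS dialects — US-style
quarterly ASCII extracts (`$`-delimited DEMO/DRUG/REAC/THER/OUTC/INDI
tables keyed by case and version identifiers) and Japanese-style CSV
extracts (DEMO/DRUG/REAC/HIST keyed by a case identification number) — but
nothing in the pipeline is drug-specific: the target drug is defined by a
name lexicon, and every other input (PT→SOC map, label-term list, IME/DME
lists) is a plain-text file.

## Cleaning model

SRS databases contain versioned resubmissions of the same case. We keep,
per case id, the version with the most recent receipt date, breaking ties
by the higher primary id (numeric comparison when both ids parse as
integers, else lexicographic; a missing receipt date sorts below any dated
version, so a dated resubmission always supersedes an undated one).
Case ids on the quarterly deleted-report lists are then removed.

Target-drug reports are those with at least one lexicon-matching drug in
the *primary suspect* role. Matching is exact after normalization (trim,
case-fold, collapse internal whitespace); substring matching is
deliberately not offered because combination-product names would create
false positives. Reports from an excluded country (default JP for the
US-style database, to avoid double counting against the Japanese database)
are dropped; a blank country is *kept* — unknown is not the excluded
country. The reporter-country field is used where both reporter and
occurrence country exist; this is configurable in the parser.

Every filter returns its drop count and the cleaning ledger asserts the
conservation identity
`assembled − deleted − country = background` and
`background − non-PS = target`, so the flow-chart of a run is
reconstructible from the manifest.

## Counting model

The analysis unit is the **drug–event pair**: a report with k distinct
preferred terms contributes k pairs (duplicate identical PTs within a
report count once). For each term at PT or SOC level the 2×2 table is

|              | target term | other terms |
|--------------|------------|-------------|
| target drug  | a          | b           |
| other drugs  | c          | d           |

with `a+b` the target drug's event total and `a+c` the term's
database-wide total. Terms with a = 0 are not emitted (no estimator is
testable there and the case-count thresholds exclude them regardless).
Degenerate tables (a zero margin) are flagged and excluded from the
frequentist estimators rather than continuity-corrected; the Bayesian
estimators remain defined because their priors regularize zero cells.

## Detectors

* **ROR** = ad/bc, 95% CI `exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d))` (Woolf).
* **PRR** = [a/(a+b)]/[c/(c+d)], with the uncorrected Pearson χ² of the
  table, computed by the shortcut `N(ad−bc)²/((a+b)(c+d)(a+c)(b+d))`
  (verified against the Σ(O−E)²/E expansion to 1e-9 on random tables).
* **BCPNN IC**: the Bate et al. (1998) closed-form posterior mean and
  variance of the information component with the standard hyperparameters
  α = β = 2, α₁ = β₁ = γ₁₁ = 1 and
  γ = γ₁₁(N+α)(N+β)/((a+b+α₁)(a+c+β₁)); IC025 = E(IC) − 2·√V(IC).
* **MGPS EBGM**: DuMouchel's empirical-Bayes gamma-Poisson shrinker.
  Counts a_i ~ Poisson(λ_i E_i) with a two-component gamma mixture prior
  on λ. The five hyperparameters are fitted by maximum marginal likelihood
  over *all* (primary-suspect drug, PT) cells of the database — not only
  the target drug's — by bounded L-BFGS-B on log/logit scale from
  DuMouchel's classic start (0.2, 0.1, 2, 4, ⅓) plus seeded random
  restarts. The mixture likelihood has a flat ridge on which quasi-Newton
  line searches stall, so the best point is polished with Nelder–Mead
  simplex steps until stationary; a fit that keeps improving materially is
  reported as non-converged (the error carries the best-so-far fit).
  The posterior is the conjugate two-gamma mixture; EBGM = 2^{E[log₂λ|a]}
  (exact via digamma) and EBGM05 solves mixture-CDF = 0.05 by Brent
  bracketing to 1e-8 relative tolerance, with evidence weights computed in
  log space. No stratification (age/sex/year) is applied.

Default thresholds (each overridable): ROR — a ≥ 3 and CI lower bound > 1;
PRR — a ≥ 3, PRR ≥ 2, χ² ≥ 4; BCPNN — IC025 > 0; MGPS — EBGM05 > 2.
A **positive signal** requires all four simultaneously. These are the
conventional criteria for this detector quartet; boundary comparisons on
the Bayesian bounds are strict.

One correction to a tempting intuition: IC and EBGM are *not* monotone in
a with b, c, d held fixed — the relative reporting ratio aN/((a+b)(a+c))
increases in a only while a² < bc and bends back toward 1 when a dominates
its margins. The property tests assert monotonicity for ROR/PRR everywhere
and for IC only in the a² < bc regime.

## Classification and priority

Positives absent from the label-term list are *unexpected*. Clinical
priority grades each positive on four 0–2-point criteria: reporting rate
(share of the target drug's PT events: >10% → 2, 1–10% → 1, <1% → 0),
stability (detectors flagging: ≥3 → 2, exactly 2 → 1, else 0 — the prose
rule; the tabular "2 of 3 / 1 of 3" variant circulating for this scheme is
internally inconsistent), case fatality (share of reports carrying the
term with a death outcome — FAERS code `DE`, JADER 死亡 — >50% → 2,
25–50% → 1, else 0; the denominator is reports, the standard reading), and
clinical relevance (Designated Medical Event → 2, Important → 1; DME wins
when a term is on both lists). Totals 0–2 / 3–5 / 6–8 map to low / medium
/ high. The reporting-rate criterion uses the PT-share-of-events
convention because that is the percentage printed beside case counts in
the reference tables.

The monotherapy sensitivity analysis keeps only target reports whose whole
drug list matches the lexicon (no concomitant or other-suspect drug of any
role) and reruns tables + detectors through the identical code path
against the unchanged background.

## Time to onset

TTO = event date − earliest lexicon-drug therapy start date, in calendar
days. Only day-precision dates qualify; month- or year-precision tokens
are excluded as imprecise, absent dates as missing, and pre-treatment
onsets as negative — the three exclusion counts plus inclusions always sum
to the candidates. When a report has several event dates the earliest
valid one is used (earliest-exposure-to-earliest-event, the conservative
reading). Quantiles use linear interpolation between order statistics; the
histogram uses 30-day bins (day-0 onsets fold into the first bin) plus a
>360-day tail.

The Weibull fit is maximum likelihood: the shape MLE solves the profile
score equation by bracketed root finding (deterministic, no iterate-
dependent start), the scale follows in closed form, and the 95% CI for the
shape comes from the observed information on the log scale, exponentiated
so bounds stay positive. Day-0 onsets are shifted to 0.5 day (configurable)
because the likelihood needs positive support. A CI entirely below 1 is
classified *early failure* (front-loaded hazard), above 1 *wear-out*,
otherwise *random failure*. Degenerate inputs (all intervals equal, or
n < 10) are rejected.

## Synthetic data generator

The generator emulates the two raw dialects from a single simulated truth
so the full pipeline is testable offline. Per report: a suspect drug
(target share 10%), a truncated-geometric number of PT draws (mean 3.15
distinct PTs per report, matching the events-per-report ratio of the
reference cohorts), drawn from a Zipf-weighted 150-term vocabulary mapped
round-robin onto 12 SOCs. A planted signal (drug, pt, λ) multiplies that
PT's draw weight by λ for that drug's reports. Background drugs carry
heterogeneous event profiles — each (background drug, PT) draw weight is
multiplied by a log-normal factor (σ = 0.5) — because real SRS
backgrounds are overdispersed relative to a single Poisson rate and the
empirical-Bayes prior is designed for exactly that regime; a perfectly
homogeneous background would make the fitted mixture collapse to a point
mass at 1 and over-shrink genuine outliers. The target drug's weights are
never perturbed, so a null configuration is exactly null for every tested
term and planted λ values are exact relative ratios. The generator
records the *expected* count of each planted pair exactly as
Σ_reports (1 − (1−p̃)^k) given the realized draw counts, which is what the
recovery tests compare against. Dates degrade with 30% missingness and 8%
month/year imprecision per field, 2% of onsets precede therapy start, and
the onset delay is Weibull (shape 0.7, scale 47.1 days → median ≈ 28 d).
Sex/age/weight/country/outcome mixes default to the reference cohort's
composition (≈46% male, 19% death outcomes, 12.5% JP-country reports so
the country exclusion has work to do). Five percent of cases get a
later-dated resubmission with a higher primary id and perturbed
demographics; 1% of case ids go on the deleted list. The Japanese-dialect
files re-express the same canonical cases in the JADER column vocabulary.

What the generator does **not** emulate: real per-term frequencies,
co-prescription structure, term co-occurrence within reports, reporting
trends over calendar time, or stratification confounders. Passing recovery
tests therefore demonstrates correctness of the estimators and plumbing
under a known mechanism, not calibration on real SRS data.

A separate hand-built 20-case fixture (`fixture_small`) exercises every
cleaning branch deterministically: a duplicate pair, a deleted case, a
JP-country report, concomitant-only and secondary-suspect-only target
mentions, a month-precision date and a negative onset interval.

## Problem sizes used in the checks

The shipped checks run at desk scale: a 50,000-report simulated database
for the null false-positive rate of the four-way rule (≤ 5% of tested
terms), 100 seeded 4,000-report replicates for λ = 10 signal recovery
(≥ 90% of seeds), 1,000 random tables per estimator-oracle comparison, and
200 seeded n = 500 fits for Weibull CI coverage (≥ 90%). Headline counts
from the reference 20-year analysis (report totals, per-term ROR/EBGM
values, signal counts) depend on the full national databases and are out
of desk-scale reach; the worked examples instead recompute every printed
*proportion* from its printed counts.

## Known limitations

- No fuzzy drug-name matching or ingredient linking; the lexicon must list
  every verbatim spelling to capture.
- No stratified or regression-adjusted disproportionality.
- The MGPS prior is fitted per database; very small backgrounds (< ~50
  cells) give unstable hyperparameters.
- TTO treats the earliest therapy start as exposure; re-challenge and
  interrupted dosing are not modelled, and there is no interval censoring.
- Percentile-based EBGM05 assumes the fitted prior; it is not a robust
  bound under prior misspecification.
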