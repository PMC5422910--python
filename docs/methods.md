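# Methods

## The phenotype and its matching semantics

An encounter is classified by a boolean combination (ALL/ANY) of clauses;
each clause asks whether the encounter's diagnostic or procedural code
set hits a named code list. The three standard variants:

| model  | rule |
|--------|------|
| model1 | any CRS ICD-10 diagnostic code (J32 chronic sinusitis family, J33 nasal polyposis family; 13 patterns) |
| model2 | any ESS CCI procedural code (therapeutic interventions on the ethmoidal/sphenoidal/maxillary/frontal/paranasal sinuses; 16 patterns) |
| model3 | model1 AND model2 (the validated definition) |

Matching is **hierarchical prefix** matching on canonical codes
(uppercase, dots stripped): pattern `J32` matches `J324`, because
published lists enumerate both parent and child rubrics and source data
may code at either granularity. CCI wildcard groups (`^^`) denote
qualifier fields with arbitrary values; a wildcard pattern matches every
code extending the text before its first wildcard group (`1.EU.52.^^` ⇒
prefix `1EU52`). `^^` is deliberately *not* read as "exactly two
characters": CCI qualifier-field lengths vary across data dialects, and
under prefix semantics the choice cannot change any result for the
enumerated lists. The pattern `1.EX.^^` (one wildcard group where its
siblings have two) normalizes to prefix `1EX` under the same rule.
Duplicated rows in the published code table are stored once — under
ANY-semantics duplicates cannot change a classification.

All diagnosis fields of an encounter are eligible (no primary-position
restriction), since the validated definition is stated without position
qualifiers. There is no NOT combinator: the validated models need none,
and negation over incompletely coded data invites silent misuse.

## Accuracy statistics

Point estimates are exact `Fraction`s; rounding happens only in the
formatter. This matters: LR+ ≈ 11,096 on the derivation table is only
reproducible from unrounded Se and Sp (0.96/0.0000865 computed from the
rounded display values is off by hundreds).

* **Binomial CIs** — Clopper–Pearson (exact beta-quantile) by default,
  matching the mid-2010s SAS convention the original analysis most
  plausibly used; Wilson score and Wald by flag. Bounds are clipped to
  [0, 1]. Backed by `statsmodels.stats.proportion.proportion_confint`;
  the test suite cross-checks Clopper–Pearson against an independent
  bisection of the binomial tail probability.
* **Likelihood-ratio CIs** — the standard log-transform (Simel-type)
  interval: exp(ln LR ± z·SE) with
  SE(ln LR+) = √(1/TP − 1/(TP+FN) + 1/FP − 1/(FP+TN)) and the analogous
  expression for LR−. This reproduces the published derivation bounds
  (6,794–18,120) and validation bounds (15.3–74.0) to within rounding.
* **Zero cells** — statistics with zero denominators are reported as
  undefined (and LR+ as +∞ when FP = 0 with Se > 0), never silently
  coerced; a 0.5 continuity correction is available by explicit flag.

**Display conventions** (the published tables' style): percentages to
one decimal, half-up; values at or above 99.95% display as "100";
nonzero percentages below 1% keep two decimals (so a 0.0019 prevalence
prints 0.19, not 0.2). Likelihood ratios ≥ 100 print as integers with a
thousands separator, [1, 100) to one decimal, below 1 to two decimals.

## The joint-count solver

The derivation cohort is characterized by, per reference stratum
(case/control), the number of encounters carrying *both* code types, a
*diagnosis only*, a *procedure only*, or *neither*. Eight integers fully
determine all three models' confusion tables: model1's TP is
both+dx-only among cases, model3's TP is the both-cell, and so on.

`solve_joint_counts` inverts the published summaries: given the final
model's full 2×2 table and the rounded (one decimal, half-up)
sensitivity/PPV of the two single-clause models, it enumerates every
integer (TP, FP) pair whose display-rounding matches each summary,
intersects with the margin constraints, and demands a unique solution
(raising `NoSolutionError` otherwise, naming the infeasible constraint).
For the published inputs the solution is unique: cases 333/2/3/9,
controls 16/8/8/184,975.

## The synthetic cohort generator

**What it emulates.** A hospital surgical-encounter table at the
code-presence level: each encounter gets a reference label (chart-review
stratum), one concrete CRS ICD-10 child code when "dx present" (drawn
uniformly from the 11 child rubrics), one concrete CCI completion when
"proc present" (a wildcard pattern's prefix plus a two-letter qualifier),
and non-matching filler codes (other ICD-10 chapters, non-sinus CCI
codes) otherwise, so controls carry realistic coded content. Ages
(18–90), dates within the labelled year, and row order are seeded draws.
Fixture realizations are deterministic in distribution: confusion tables
depend only on the counts, never the seed — a property test asserts it.

**What it does not emulate.** The chart-review process itself
(indication adjudication, the recurrent-sinusitis re-review), real
co-occurrence patterns of specific codes (unreported in the source),
multiple encounters per patient, comorbidity/length-of-stay structure,
and coding error processes. Passing tests therefore demonstrate the
*arithmetic* fidelity of the pipeline — classification, tabulation,
statistics — not that the phenotype would transport to another centre;
the PPV in particular is prevalence-bound (see `ppv_at_prevalence`).

**Parametric mode** draws per-stratum code presence as (optionally
φ-correlated, via Fréchet-clipped joint cells) Bernoulli pairs, for
power and robustness experiments; empirical model1 sensitivity recovers
the generating probability within 3 binomial SDs at n = 10⁴ (tested).

**Internal-validation design.** `sample_validation_cohort` takes every
model-predicted case plus a seeded uniform sample (without replacement)
of n predicted controls — the design that yields the published
392-encounter validation table. The validation-year fixture places its
two false negatives in the case/dx-only stratum (CRS diagnosis coded,
procedure code absent); the published table does not disclose their true
pattern, and any non-both stratum yields identical cells. Linkage
attrition (10 cases, 3 controls lost) is emulated by seeded per-stratum
removal in `apply_attrition`.

## Other design choices

* The age rule (≥ 18) was a cohort-inclusion criterion, not part of the
  coded model, so `filter_adults` retains encounters with *missing* age
  (with a logged warning) rather than excluding them.
* Algorithms are data (JSON), not code, so variants are cheap to author
  and audit; seeds are mandatory in every stochastic operation.
* The ICD-9 list (473/471 families) is carried as data only, for users
  defining analogous historical phenotypes; no ICD-9↔ICD-10 crosswalk is
  attempted.
* Problem sizes in the test and acceptance runs are the study's own:
  185,354 derivation encounters, 392 validation encounters, 10⁴–10⁵ per
  stratum for parametric recovery checks.

## Known limitations

* Single-centre structure: the generator reproduces one hospital's
  confusion structure; external transportability is exactly what it
  cannot show.
* The source analysis's CI procedure is unreported; Clopper–Pearson
  reproduces the printed proportion bounds only to ~0.1 percentage
  point, so CI bounds are treated as approximate reproductions, not
  exact targets (the tests bound them at 0.2% relative).
* The likelihood-ratio interval relies on the asymptotic normality of
  ln LR; with a 16-count FP cell it is serviceable, with smaller cells
  prefer the continuity-corrected variant or report undefined.
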