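# esscrs

Administrative-data phenotyping of **endoscopic sinus surgery for chronic
rhinosinusitis (ESS-CRS)**: rule-based encounter classifiers over ICD-10
diagnostic and CCI procedural codes, the full diagnostic-accuracy toolkit
(2×2 tables, Se/Sp/PPV/NPV, likelihood ratios, exact and score confidence
intervals), and a synthetic cohort generator that reproduces published
validation structures exactly.

## Who this is for

Health-services researchers who identify surgical populations inside
administrative claims data need validated code-based case definitions:
a rule over coded diagnoses and procedures that stands in for chart-review
ground truth. This package implements and validates one such definition —
an encounter is an ESS-CRS case iff it carries **at least one CRS ICD-10
diagnostic code (J32/J33 families) AND at least one ESS CCI procedural
code (sinus-intervention families 1.EU/1.EV/1.EW/1.EX/1.EY)** — together
with the two single-clause variants (diagnosis-only, procedure-only), and
provides the statistical machinery to validate any such rule against a
labelled reference cohort.

## The statistics

Against a reference standard, a binary rule yields a 2×2 table
(TP/FP/FN/TN) and

```
Se  = TP/(TP+FN)        Sp  = TN/(TN+FP)
PPV = TP/(TP+FP)        NPV = TN/(TN+FN)
LR+ = Se/(1−Sp)         LR− = (1−Se)/Sp
prevalence = (TP+FN)/N
```

Point estimates are exact rationals, rounded only at display. Binomial
CIs are Clopper–Pearson by default (Wilson and Wald by flag); likelihood
ratios use the log-transform interval exp(ln LR ± z·SE) with
SE(ln LR+) = √(1/TP − 1/(TP+FN) + 1/FP − 1/(FP+TN)).

Because case prevalence in a surgical cohort is tiny (~0.19%), PPV is
prevalence-fragile; `ppv_at_prevalence(se, sp, prev)` projects the rule
to centres with a different case mix via Bayes' theorem.

## Worked example

```python
import esscrs as E

# Reconstruct the derivation cohort's joint code-presence counts from
# the published rounded model summaries + the final model's 2x2 table,
# realize 185,354 coded encounters, classify, and validate.
fixture = E.derivation_fixture()
cohort = E.realize_cohort(fixture, seed=1)

clf = E.PhenotypeClassifier(algorithm="model3").fit(cohort)
labels = clf.predict_labels(cohort)
table = E.build_confusion(labels,
                          {e.encounter_id: e.reference_label for e in cohort})
print(table)
print(E.accuracy_report(table).formatted)
```

prints

```
ConfusionTable(tp=333, fp=16, fn=14, tn=184991)
{'sensitivity': '96.0', 'sensitivity_ci': '93.3-97.8',
 'specificity': '100', 'specificity_ci': '100-100',
 'ppv': '95.4', 'ppv_ci': '92.7-97.4',
 'npv': '100', 'npv_ci': '100-100',
 'prevalence': '0.19', 'prevalence_ci': '0.17-0.21',
 'lr_positive': '11,096', 'lr_positive_ci': '6,795-18,121',
 'lr_negative': '0.04', 'lr_negative_ci': '0.02-0.07'}
```

i.e. the final model misses 14 of 347 true ESS-CRS encounters
(sensitivity 96.0%), flags 16 false positives among 185,007 controls
(specificity rounds to 100%), and a positive classification multiplies
the odds of true case status about 11,000-fold. `PhenotypeClassifier`
is a scikit-learn estimator (`fit`/`predict`/`get_params`), so it
composes with sklearn model-selection tooling; `apply_algorithm` and
`classify_encounter` are functional wrappers.

The same workflow runs from the shell — each validation table is one
command:

```bash
esscrs simulate --fixture validation --seed 3 --out validation.csv
esscrs validate --input validation.csv --compare-models --out report/
esscrs report --tp 333 --fp 16 --fn 14 --tn 184991
```

Custom phenotype algorithms are data, not code: JSON documents naming
ALL/ANY combinations of code-list clauses (see `esscrs.load_algorithm`).

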