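"""Published validation results for the ESS-CRS phenotype, as data.

These are the printed 2x2 tables and rounded model summaries from the
original single-centre validation study (The Ottawa Hospital, surgical
encounters 2011-2012 for derivation, 2013 for internal validation).
They are inputs to the joint-count solver and to the synthetic cohort
generator, never outputs of this package.
"""

from .metrics import ConfusionTable

#: Derivation cohort reference-standard totals after linkage.
DERIVATION_CASES = 347
DERIVATION_CONTROLS = 185_007
DERIVATION_TOTAL = DERIVATION_CASES + DERIVATION_CONTROLS  # 185,354

#: Chart-review flow before linkage: 411 screened, 394 with at least
#: endoscopic antrostomy/ethmoidectomy, 357 cases; 10 cases and 3
#: controls lost in linkage.
CHART_REVIEW_CASES = 357
LINKAGE_LOST_CASES = 10
LINKAGE_LOST_CONTROLS = 3

#: Final model (diagnosis AND procedure) vs reference standard,
#: derivation cohort.
DERIVATION_TABLE = ConfusionTable(tp=333, fp=16, fn=14, tn=184_991)

#: Internal validation (2013): all model-identified cases plus 200
#: randomly selected model-identified controls.
VALIDATION_TABLE = ConfusionTable(tp=186, fp=6, fn=2, tn=198)
VALIDATION_N_SAMPLED_CONTROLS = 200

#: Rounded (sensitivity %, PPV %) for the three model variants as
#: printed in the model-comparison table.
MODEL_SUMMARIES: dict[str, tuple[float, float]] = {
    "model1": (96.5, 93.3),
    "model2": (96.8, 93.3),
    "model3": (96.0, 95.4),
}
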