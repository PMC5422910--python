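"""Confusion tables, validation statistics, confidence intervals, display."""

import math
from fractions import Fraction

import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import brentq
from scipy.stats import binom

from esscrs.errors import InputError
from esscrs.metrics import (
    ConfusionTable,
    accuracy_report,
    build_confusion,
    ci_likelihood_ratio,
    ci_proportion,
    format_lr,
    format_percent,
    lr_negative,
    lr_positive,
    npv,
    ppv,
    ppv_at_prevalence,
    prevalence,
    sensitivity,
    specificity,
)
from esscrs.phenotype import PredictedLabel

DERIVATION = ConfusionTable(tp=333, fp=16, fn=14, tn=184_991)
VALIDATION = ConfusionTable(tp=186, fp=6, fn=2, tn=198)

_tables = st.builds(
    ConfusionTable,
    tp=st.integers(0, 60), fp=st.integers(0, 60),
    fn=st.integers(0, 60), tn=st.integers(0, 60),
).filter(lambda t: t.total > 0)


class TestBuildConfusion:
    def test_perfect_agreement(self):
        labels = {"a": "case", "b": "control", "c": "case"}
        t = build_confusion(labels, labels)
        assert (t.tp, t.fp, t.fn, t.tn) == (2, 0, 0, 1)

    def test_from_predicted_label_objects(self):
        pred = [PredictedLabel("a", "case"), PredictedLabel("b", "case")]
        ref = {"a": "case", "b": "control"}
        t = build_confusion(pred, ref)
        assert (t.tp, t.fp, t.fn, t.tn) == (1, 1, 0, 0)

    def test_id_mismatch_rejected(self):
        with pytest.raises(InputError, match="id mismatch"):
            build_confusion({"a": "case"}, {"b": "case"})

    def test_unknown_reference_rejected(self):
        with pytest.raises(InputError, match="reference label"):
            build_confusion({"a": "case"}, {"a": "unknown"})

    @given(st.lists(st.tuples(st.sampled_from(["case", "control"]),
                              st.sampled_from(["case", "control"])),
                    min_size=1, max_size=30))
    def test_counts_conserved(self, pairs):
        pred = {str(i): p for i, (p, _) in enumerate(pairs)}
        ref = {str(i): r for i, (_, r) in enumerate(pairs)}
        assert build_confusion(pred, ref).total == len(pairs)


class TestPointEstimates:
    def test_derivation_table(self):
        assert sensitivity(DERIVATION) == Fraction(333, 347)
        assert specificity(DERIVATION) == Fraction(184_991, 185_007)
        assert ppv(DERIVATION) == Fraction(333, 349)
        assert prevalence(DERIVATION) == Fraction(347, 185_354)
        assert format_percent(sensitivity(DERIVATION)) == "96.0"
        assert format_percent(ppv(DERIVATION)) == "95.4"
        assert format_percent(specificity(DERIVATION)) == "100"
        assert format_percent(prevalence(DERIVATION)) == "0.19"

    def test_validation_table(self):
        assert ppv(VALIDATION) == Fraction(186, 192)
        assert format_percent(sensitivity(VALIDATION)) == "98.9"
        assert format_percent(specificity(VALIDATION)) == "97.1"
        assert format_percent(ppv(VALIDATION)) == "96.9"

    def test_zero_sensitivity_is_zero_not_undefined(self):
        t = ConfusionTable(tp=0, fp=0, fn=5, tn=5)
        assert sensitivity(t) == 0
        assert ppv(t) is None  # no predicted positives: undefined

    def test_undefined_flagged_as_none(self):
        no_ref_controls = ConfusionTable(tp=3, fp=0, fn=2, tn=0)
        assert specificity(no_ref_controls) is None
        no_pred_controls = ConfusionTable(tp=3, fp=2, fn=0, tn=0)
        assert npv(no_pred_controls) is None

    def test_negative_counts_rejected(self):
        with pytest.raises(InputError):
            ConfusionTable(tp=-1, fp=0, fn=0, tn=1)


class TestLikelihoodRatios:
    def test_derivation_values(self):
        assert format_lr(lr_positive(DERIVATION)) == "11,096"
        assert format_lr(lr_negative(DERIVATION)) == "0.04"

    def test_validation_values(self):
        assert format_lr(lr_positive(VALIDATION)) == "33.6"
        assert format_lr(lr_negative(VALIDATION)) == "0.01"

    def test_perfect_specificity_gives_infinity(self):
        t = ConfusionTable(tp=5, fp=0, fn=1, tn=10)
        assert math.isinf(lr_positive(t))

    def test_undefined_when_no_controls(self):
        t = ConfusionTable(tp=5, fp=0, fn=1, tn=0)
        assert lr_positive(t) is None and lr_negative(t) is None


class TestProportionCI:
    def test_clopper_pearson_boundaries(self):
        assert ci_proportion(0, 20, "clopper_pearson").lower == 0.0
        assert ci_proportion(20, 20, "clopper_pearson").upper == 1.0

    def test_clopper_pearson_derivation_sensitivity(self):
        ci = ci_proportion(333, 347, "clopper_pearson", 0.95)
        assert ci.lower == pytest.approx(0.932, abs=2e-3)
        assert ci.upper == pytest.approx(0.977, abs=2e-3)

    @pytest.mark.parametrize("k, n", [
        (0, 7), (1, 7), (3, 7), (7, 7), (5, 50), (25, 50), (49, 50),
    ])
    def test_clopper_pearson_matches_tail_bisection(self, k, n):
        """Oracle: invert the binomial tail probabilities directly."""
        ci = ci_proportion(k, n, "clopper_pearson", 0.95)
        if k > 0:
            lo = brentq(lambda p: binom.sf(k - 1, n, p) - 0.025, 1e-12, 1 - 1e-12,
                        xtol=1e-12)
            assert ci.lower == pytest.approx(lo, abs=1e-6)
        else:
            assert ci.lower == 0.0
        if k < n:
            hi = brentq(lambda p: binom.cdf(k, n, p) - 0.025, 1e-12, 1 - 1e-12,
                        xtol=1e-12)
            assert ci.upper == pytest.approx(hi, abs=1e-6)
        else:
            assert ci.upper == 1.0

    @pytest.mark.parametrize("method", ["clopper_pearson", "wilson", "wald"])
    @given(k=st.integers(0, 40), n=st.integers(1, 40),
           level=st.sampled_from([0.80, 0.90, 0.95]))
    def test_contains_estimate_and_widens_with_level(self, method, k, n, level):
        if k > n:
            k = n
        ci = ci_proportion(k, n, method, level)
        assert 0 <= ci.lower <= ci.upper <= 1
        if method != "wald":  # Wald can fall outside at the boundaries
            assert ci.lower - 1e-12 <= k / n <= ci.upper + 1e-12
        wider = ci_proportion(k, n, method, level + 0.04)
        assert wider.lower <= ci.lower + 1e-12
        assert wider.upper >= ci.upper - 1e-12

    def test_invalid_arguments_rejected(self):
        with pytest.raises(InputError):
            ci_proportion(5, 3)
        with pytest.raises(InputError):
            ci_proportion(1, 3, level=1.2)
        with pytest.raises(InputError):
            ci_proportion(1, 3, method="bogus")


class TestLikelihoodRatioCI:
    def test_derivation_lr_positive(self):
        ci = ci_likelihood_ratio(DERIVATION, "positive")
        assert ci.lower == pytest.approx(6795, rel=1e-3)
        assert ci.upper == pytest.approx(18121, rel=1e-3)

    def test_derivation_lr_negative(self):
        ci = ci_likelihood_ratio(DERIVATION, "negative")
        assert ci.lower == pytest.approx(0.0242, abs=5e-4)
        assert ci.upper == pytest.approx(0.0674, abs=5e-4)

    def test_uninformative_table_contains_one(self):
        t = ConfusionTable(10, 10, 10, 10)
        assert ci_likelihood_ratio(t, "positive").contains(1.0)
        assert ci_likelihood_ratio(t, "negative").contains(1.0)

    def test_zero_cell_undefined_unless_continuity(self):
        t = ConfusionTable(tp=5, fp=0, fn=1, tn=10)
        assert ci_likelihood_ratio(t, "positive") is None
        cc = ci_likelihood_ratio(t, "positive", continuity=True)
        assert cc is not None and cc.lower > 0


class TestPPVAtPrevalence:
    @given(_tables.filter(lambda t: t.tp + t.fp > 0
                          and t.tp + t.fn > 0 and t.fp + t.tn > 0))
    def test_identity_with_table_prevalence(self, t):
        got = ppv_at_prevalence(float(sensitivity(t)), float(specificity(t)),
                                float(prevalence(t)))
        assert got == pytest.approx(float(ppv(t)), abs=1e-12)

    def test_degenerate_corners(self):
        assert ppv_at_prevalence(0.5, 0.5, 1.0) == 1.0
        assert ppv_at_prevalence(0.9, 1.0, 0.001) == 1.0
        assert ppv_at_prevalence(0.0, 1.0, 0.0) is None
        with pytest.raises(InputError):
            ppv_at_prevalence(1.5, 0.5, 0.5)


@given(_tables)
def test_label_swap_symmetry(t):
    """Swapping predicted case/control swaps tp<->fp and fn<->tn, so the
    swapped sensitivity is the original false-positive rate."""
    swapped = ConfusionTable(tp=t.fp, fp=t.tp, fn=t.tn, tn=t.fn)
    if t.fp + t.tn > 0:
        assert sensitivity(swapped) == Fraction(t.fp, t.fp + t.tn)


class TestFormatting:
    @pytest.mark.parametrize("value, expected", [
        (Fraction(333, 347), "96.0"),
        (0.9999135, "100"),
        (0.9995, "100"),
        (0.99949, "99.9"),
        (0.0018721, "0.19"),
        (0.5, "50.0"),
        (0.0, "0.0"),
        (None, "undefined"),
    ])
    def test_percent(self, value, expected):
        assert format_percent(value) == expected

    @pytest.mark.parametrize("value, expected", [
        (11096.42, "11,096"),
        (33.638, "33.6"),
        (0.04035, "0.04"),
        (0.01096, "0.01"),
        (math.inf, "inf"),
        (None, "undefined"),
    ])
    def test_lr(self, value, expected):
        assert format_lr(value) == expected


class TestAccuracyReport:
    def test_full_report_round_trips_to_files(self, tmp_path):
        rep = accuracy_report(VALIDATION)
        fmt = rep.formatted
        assert fmt["sensitivity"] == "98.9" and fmt["lr_positive"] == "33.6"
        rep.to_json(tmp_path / "r.json")
        rep.to_csv(tmp_path / "r.csv")
        assert "96.9" in (tmp_path / "r.csv").read_text()

    def test_cis_contain_estimates(self):
        rep = accuracy_report(DERIVATION)
        for name in ("sensitivity", "specificity", "ppv", "npv", "prevalence"):
            est = getattr(rep, name)
            assert est.ci.contains(est.as_float)
        assert rep.lr_positive.ci.contains(rep.lr_positive.value)

    def test_empty_table_rejected(self):
        with pytest.raises(InputError):
            accuracy_report(ConfusionTable(0, 0, 0, 0))
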