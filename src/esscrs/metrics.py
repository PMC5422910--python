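"""Diagnostic-accuracy statistics for binary phenotype validation.

A predicted case/control labelling is compared against a chart-review
reference standard in a 2x2 confusion table, from which sensitivity,
specificity, predictive values, prevalence and likelihood ratios are
computed with confidence intervals:

* Se = TP/(TP+FN), Sp = TN/(TN+FP), PPV = TP/(TP+FP), NPV = TN/(TN+FN)
* LR+ = Se/(1-Sp), LR- = (1-Se)/Sp
* prevalence = (TP+FN)/N

Point estimates are exact rationals; rounding happens only at display
time. Binomial confidence intervals use Clopper-Pearson (exact) by
default, with Wilson score and Wald available. Likelihood-ratio
intervals use the standard log-transform (Simel-type) standard error

    SE(ln LR+) = sqrt(1/TP - 1/(TP+FN) + 1/FP - 1/(FP+TN))

and analogously for LR-, exponentiating ln LR +/- z * SE.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from pathlib import Path
from typing import Mapping

from scipy.stats import norm
from statsmodels.stats.proportion import proportion_confint

from .errors import InputError
from .phenotype import CASE, CONTROL, PredictedLabel

__all__ = [
    "ConfusionTable",
    "ConfidenceInterval",
    "Estimate",
    "AccuracyReport",
    "build_confusion",
    "sensitivity",
    "specificity",
    "ppv",
    "npv",
    "prevalence",
    "lr_positive",
    "lr_negative",
    "ci_proportion",
    "ci_likelihood_ratio",
    "ppv_at_prevalence",
    "accuracy_report",
    "format_report",
    "format_percent",
    "format_lr",
]

CI_METHODS = {"wald": "normal", "wilson": "wilson", "clopper_pearson": "beta"}


@dataclass(frozen=True)
class ConfusionTable:
    """TP/FP/FN/TN counts from predicted vs reference labels."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or v < 0:
                raise InputError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def predicted_cases(self) -> int:
        return self.tp + self.fp

    @property
    def reference_cases(self) -> int:
        return self.tp + self.fn


def _as_label_map(labels) -> dict[str, str]:
    if isinstance(labels, Mapping):
        return dict(labels)
    out = {}
    for item in labels:
        if isinstance(item, PredictedLabel):
            out[item.encounter_id] = item.label
        else:
            k, v = item
            out[str(k)] = v
    return out


def build_confusion(predicted, reference) -> ConfusionTable:
    """Cross-tabulate predicted vs reference labels into a 2x2 table.

    Both arguments may be mappings id -> label, sequences of
    ``(id, label)`` pairs, or sequences of :class:`PredictedLabel`. The id
    sets must coincide and reference labels must be ``case``/``control``.
    """
    pred = _as_label_map(predicted)
    ref = _as_label_map(reference)
    if set(pred) != set(ref):
        missing = set(pred) ^ set(ref)
        raise InputError(f"id mismatch between predicted and reference "
                         f"labels ({len(missing)} unmatched)")
    tp = fp = fn = tn = 0
    for eid, r in ref.items():
        if r not in (CASE, CONTROL):
            raise InputError(f"reference label for {eid!r} must be "
                             f"case/control, got {r!r}")
        p = pred[eid]
        if p == CASE:
            tp += r == CASE
            fp += r == CONTROL
        else:
            fn += r == CASE
            tn += r == CONTROL
    return ConfusionTable(tp, fp, fn, tn)


def _ratio(num: int, den: int) -> Fraction | None:
    return Fraction(num, den) if den > 0 else None


def sensitivity(t: ConfusionTable) -> Fraction | None:
    return _ratio(t.tp, t.tp + t.fn)


def specificity(t: ConfusionTable) -> Fraction | None:
    return _ratio(t.tn, t.tn + t.fp)


def ppv(t: ConfusionTable) -> Fraction | None:
    return _ratio(t.tp, t.tp + t.fp)


def npv(t: ConfusionTable) -> Fraction | None:
    return _ratio(t.tn, t.tn + t.fn)


def prevalence(t: ConfusionTable) -> Fraction | None:
    return _ratio(t.tp + t.fn, t.total)


def lr_positive(t: ConfusionTable) -> float | None:
    """Positive likelihood ratio; +inf when FP = 0 (perfect specificity)."""
    se, sp = sensitivity(t), specificity(t)
    if se is None or sp is None:
        return None
    if sp == 1:
        return math.inf if se > 0 else None
    return float(se / (1 - sp))


def lr_negative(t: ConfusionTable) -> float | None:
    se, sp = sensitivity(t), specificity(t)
    if se is None or sp is None or sp == 0:
        return None
    return float((1 - se) / sp)


@dataclass(frozen=True)
class ConfidenceInterval:
    lower: float
    upper: float
    level: float
    method: str

    def __post_init__(self) -> None:
        if not self.lower <= self.upper:
            raise InputError(f"CI lower {self.lower} > upper {self.upper}")

    def contains(self, x: float) -> bool:
        return self.lower <= x <= self.upper


def ci_proportion(successes: int, n: int, method: str = "clopper_pearson",
                  level: float = 0.95) -> ConfidenceInterval:
    """Binomial confidence interval for ``successes`` out of ``n``.

    ``method`` is one of ``clopper_pearson`` (exact), ``wilson`` (score)
    or ``wald`` (normal approximation); bounds are clipped to [0, 1].
    """
    if not 0 <= successes <= n or n <= 0:
        raise InputError(f"need 0 <= successes <= n with n > 0, "
                         f"got {successes}/{n}")
    if not 0 < level < 1:
        raise InputError(f"level must be in (0, 1), got {level}")
    if method not in CI_METHODS:
        raise InputError(f"unknown CI method {method!r}")
    lo, hi = proportion_confint(successes, n, alpha=1 - level,
                                method=CI_METHODS[method])
    return ConfidenceInterval(max(0.0, float(lo)), min(1.0, float(hi)),
                              level, method)


def ci_likelihood_ratio(t: ConfusionTable, which: str = "positive",
                        level: float = 0.95,
                        continuity: bool = False) -> ConfidenceInterval | None:
    """Log-method confidence interval for a likelihood ratio.

    Returns ``None`` when a required cell is zero (the interval is
    undefined), unless ``continuity`` adds 0.5 to every cell.
    """
    if which not in ("positive", "negative"):
        raise InputError(f"which must be positive/negative, got {which!r}")
    tp, fp, fn, tn = float(t.tp), float(t.fp), float(t.fn), float(t.tn)
    if continuity and 0 in (t.tp, t.fp, t.fn, t.tn):
        tp, fp, fn, tn = tp + 0.5, fp + 0.5, fn + 0.5, tn + 0.5
    n1, n0 = tp + fn, fp + tn
    if which == "positive":
        if tp == 0 or fp == 0:
            return None
        lr = (tp / n1) / (fp / n0)
        se = math.sqrt(1 / tp - 1 / n1 + 1 / fp - 1 / n0)
    else:
        if fn == 0 or tn == 0:
            return None
        lr = (fn / n1) / (tn / n0)
        se = math.sqrt(1 / fn - 1 / n1 + 1 / tn - 1 / n0)
    z = norm.ppf(0.5 + level / 2)
    return ConfidenceInterval(lr * math.exp(-z * se), lr * math.exp(z * se),
                              level, "log_lr")


def ppv_at_prevalence(sens: float, spec: float, prev: float) -> float | None:
    """Positive predictive value at a hypothetical prevalence (Bayes).

    PPV = Se*p / (Se*p + (1-Sp)*(1-p)). Useful for projecting the model
    to centres with a different case mix. Returns ``None`` when the
    denominator is zero (no predicted positives at that prevalence).
    """
    for name, v in (("sens", sens), ("spec", spec), ("prev", prev)):
        if not 0 <= v <= 1:
            raise InputError(f"{name} must be in [0, 1], got {v}")
    num = sens * prev
    den = num + (1 - spec) * (1 - prev)
    if den == 0:
        return None
    return num / den


# -- formatting ---------------------------------------------------------

def _half_up(x: Decimal, places: int) -> Decimal:
    q = Decimal(1).scaleb(-places)
    return x.quantize(q, rounding=ROUND_HALF_UP)


def _to_decimal(x) -> Decimal:
    if isinstance(x, Fraction):
        return Decimal(x.numerator) / Decimal(x.denominator)
    return Decimal(str(float(x)))


def format_percent(p) -> str:
    """Display a proportion as a percentage string.

    One decimal by default; values at or above 0.9995 display as "100";
    nonzero values below 1% keep two decimals (matching the convention
    for very low prevalences).
    """
    if p is None:
        return "undefined"
    d = _to_decimal(p) * 100
    if d >= Decimal("99.95"):
        return "100"
    if 0 < d < 1:
        return str(_half_up(d, 2))
    return str(_half_up(d, 1))


def format_lr(x) -> str:
    """Display a likelihood ratio: >=100 to the nearest integer with a
    thousands separator, [1, 100) to one decimal, below 1 to two."""
    if x is None:
        return "undefined"
    if math.isinf(x):
        return "inf"
    d = _to_decimal(x)
    if d >= 100:
        return f"{int(_half_up(d, 0)):,}"
    if d >= 1:
        return str(_half_up(d, 1))
    return str(_half_up(d, 2))


@dataclass(frozen=True)
class Estimate:
    """A point estimate with its confidence interval (either may be None)."""

    value: object  # Fraction, float, or None when undefined
    ci: ConfidenceInterval | None = None

    @property
    def as_float(self) -> float | None:
        return None if self.value is None else float(self.value)


@dataclass(frozen=True)
class AccuracyReport:
    """All validation statistics for one confusion table."""

    table: ConfusionTable
    sensitivity: Estimate
    specificity: Estimate
    ppv: Estimate
    npv: Estimate
    prevalence: Estimate
    lr_positive: Estimate
    lr_negative: Estimate
    ci_method: str
    level: float

    @property
    def formatted(self) -> dict[str, str]:
        return format_report(self)

    def to_dict(self) -> dict:
        out: dict = {
            "table": {"tp": self.table.tp, "fp": self.table.fp,
                      "fn": self.table.fn, "tn": self.table.tn},
            "ci_method": self.ci_method,
            "level": self.level,
        }
        for name in ("sensitivity", "specificity", "ppv", "npv",
                     "prevalence", "lr_positive", "lr_negative"):
            est: Estimate = getattr(self, name)
            out[name] = {
                "estimate": est.as_float,
                "lower": est.ci.lower if est.ci else None,
                "upper": est.ci.upper if est.ci else None,
            }
        out["formatted"] = self.formatted
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def to_csv(self, path: str | Path) -> None:
        fmt = self.formatted
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["statistic", "estimate", "lower", "upper", "formatted"])
            for name in ("sensitivity", "specificity", "ppv", "npv",
                         "prevalence", "lr_positive", "lr_negative"):
                est: Estimate = getattr(self, name)
                w.writerow([
                    name, est.as_float,
                    est.ci.lower if est.ci else "",
                    est.ci.upper if est.ci else "",
                    fmt[name],
                ])


def _prop_estimate(num: int, den: int, method: str, level: float) -> Estimate:
    value = _ratio(num, den)
    ci = ci_proportion(num, den, method, level) if den > 0 else None
    return Estimate(value, ci)


def accuracy_report(t: ConfusionTable, ci_method: str = "clopper_pearson",
                    level: float = 0.95) -> AccuracyReport:
    """Compute every validation statistic for a confusion table.

    Undefined statistics (zero denominators, zero LR cells) are flagged
    as ``None`` rather than coerced to a number.
    """
    if t.total <= 0:
        raise InputError("confusion table is empty")
    return AccuracyReport(
        table=t,
        sensitivity=_prop_estimate(t.tp, t.tp + t.fn, ci_method, level),
        specificity=_prop_estimate(t.tn, t.tn + t.fp, ci_method, level),
        ppv=_prop_estimate(t.tp, t.tp + t.fp, ci_method, level),
        npv=_prop_estimate(t.tn, t.tn + t.fn, ci_method, level),
        prevalence=_prop_estimate(t.tp + t.fn, t.total, ci_method, level),
        lr_positive=Estimate(lr_positive(t), ci_likelihood_ratio(t, "positive", level)),
        lr_negative=Estimate(lr_negative(t), ci_likelihood_ratio(t, "negative", level)),
        ci_method=ci_method,
        level=level,
    )


def format_report(r: AccuracyReport) -> dict[str, str]:
    """Render a report as display strings, e.g. Se "96.0 (93.2-97.7)"."""
    out: dict[str, str] = {}
    for name in ("sensitivity", "specificity", "ppv", "npv", "prevalence"):
        est: Estimate = getattr(r, name)
        out[name] = format_percent(est.value)
        if est.ci is not None:
            out[f"{name}_ci"] = (f"{format_percent(est.ci.lower)}-"
                                 f"{format_percent(est.ci.upper)}")
    for name in ("lr_positive", "lr_negative"):
        est = getattr(r, name)
        out[name] = format_lr(est.value)
        if est.ci is not None:
            out[f"{name}_ci"] = (f"{format_lr(est.ci.lower)}-"
                                 f"{format_lr(est.ci.upper)}")
    return out
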