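"""Synthetic surgical-encounter cohorts.

Two generation modes:

* **fixture mode** — a :class:`JointCountFixture` pins, per reference
  stratum (case/control), how many encounters carry both a CRS diagnosis
  code and an ESS procedure code, a diagnosis only, a procedure only, or
  neither. Realizing a fixture yields a cohort whose Model 1/2/3
  confusion tables are fully determined by the counts, whatever the seed
  (the seed only varies which concrete codes appear and the row order).
  :func:`solve_joint_counts` reconstructs the fixture for the published
  derivation cohort from the rounded per-model summaries plus the final
  model's 2x2 table, by exhaustive integer search with a uniqueness
  check.

* **parametric mode** — free per-stratum code-presence probabilities
  with an optional within-stratum correlation, for power/robustness
  experiments at arbitrary cohort sizes.

Also provides the internal-validation sampling design (all predicted
cases plus a seeded random sample of predicted controls) and linkage
attrition emulation.
"""

from __future__ import annotations

import datetime as _dt
import itertools
from dataclasses import asdict, dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np

from .errors import InputError, NoSolutionError
from .matching import ESS_CCI, get_code_list
from .metrics import ConfusionTable
from .phenotype import CASE, CONTROL, Encounter, PhenotypeAlgorithm, apply_algorithm
from . import published

__all__ = [
    "StratumCounts",
    "JointCountFixture",
    "GeneratorParams",
    "solve_joint_counts",
    "derivation_fixture",
    "validation_year_fixture",
    "realize_cohort",
    "parametric_generate",
    "sample_validation_cohort",
    "apply_attrition",
]

STRATA = ("both", "dx_only", "proc_only", "neither")


@dataclass(frozen=True)
class StratumCounts:
    """Joint code-presence counts within one reference stratum."""

    both: int
    dx_only: int
    proc_only: int
    neither: int

    def __post_init__(self) -> None:
        for k in STRATA:
            if getattr(self, k) < 0:
                raise InputError(f"negative stratum count: {k}")

    @property
    def total(self) -> int:
        return self.both + self.dx_only + self.proc_only + self.neither

    @property
    def with_dx(self) -> int:
        return self.both + self.dx_only

    @property
    def with_proc(self) -> int:
        return self.both + self.proc_only


@dataclass(frozen=True)
class JointCountFixture:
    """Exact joint code-presence structure for a case/control cohort."""

    cases: StratumCounts
    controls: StratumCounts
    year_label: str = ""

    @property
    def total(self) -> int:
        return self.cases.total + self.controls.total

    def expected_confusion(self, model: str) -> ConfusionTable:
        """The confusion table any realization must produce for a model."""
        c, k = self.cases, self.controls
        if model == "model1":
            tp, fp = c.with_dx, k.with_dx
        elif model == "model2":
            tp, fp = c.with_proc, k.with_proc
        elif model == "model3":
            tp, fp = c.both, k.both
        else:
            raise InputError(f"unknown model {model!r}")
        return ConfusionTable(tp=tp, fp=fp, fn=c.total - tp, tn=k.total - fp)

    def to_dict(self) -> dict:
        return {"cases": asdict(self.cases), "controls": asdict(self.controls),
                "year_label": self.year_label}

    @classmethod
    def from_dict(cls, d: dict) -> "JointCountFixture":
        return cls(StratumCounts(**d["cases"]), StratumCounts(**d["controls"]),
                   d.get("year_label", ""))


def _round1(num: int, den: int) -> float:
    """Percentage rounded half-up to one decimal, the display convention
    assumed for the published summaries."""
    d = Decimal(num) / Decimal(den) * 100
    return float(d.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _tp_candidates(sens_pct: float, n_cases: int) -> list[int]:
    return [tp for tp in range(n_cases + 1) if _round1(tp, n_cases) == sens_pct]


def _fp_candidates(ppv_pct: float, tp: int, n_controls: int) -> list[int]:
    if tp == 0:
        return []
    # PPV rounds to ppv_pct iff tp/(tp+fp) lies in [ppv-0.05, ppv+0.05);
    # bound the admissible predicted-positive totals, then verify.
    lo_frac = (ppv_pct - 0.06) / 100
    n_hi = int(tp / lo_frac) + 2 if lo_frac > 0 else tp + n_controls
    out = []
    for total in range(tp, min(n_hi, tp + n_controls) + 1):
        if _round1(tp, total) == ppv_pct:
            out.append(total - tp)
    return out


def solve_joint_counts(
    model_summaries: Mapping[str, tuple[float, float]],
    reference_totals: tuple[int, int],
    final_model_table: ConfusionTable,
) -> JointCountFixture:
    """Reconstruct the joint code-presence counts of the derivation cohort.

    Parameters
    ----------
    model_summaries : mapping
        ``{"model1": (sens_pct, ppv_pct), "model2": (...)}`` — the rounded
        (one decimal, half-up) published summaries of the single-clause
        models.
    reference_totals : (n_cases, n_controls)
    final_model_table : ConfusionTable
        The published 2x2 table of the conjunction model (model3).

    Returns the unique :class:`JointCountFixture` whose implied Model 1/2
    TP and FP reproduce the rounded summaries and whose Model 3 cells
    equal the given table. Raises :class:`NoSolutionError` if no integer
    solution exists or the solution is not unique.
    """
    n_cases, n_controls = reference_totals
    if n_cases <= 0 or n_controls <= 0:
        raise InputError("reference totals must be positive")
    if final_model_table.reference_cases != n_cases or \
            final_model_table.fp + final_model_table.tn != n_controls:
        raise NoSolutionError(
            "final model table margins disagree with reference totals",
            constraint="margins")

    per_model: dict[str, list[tuple[int, int]]] = {}
    for model in ("model1", "model2"):
        sens_pct, ppv_pct = model_summaries[model]
        pairs = [(tp, fp)
                 for tp in _tp_candidates(sens_pct, n_cases)
                 for fp in _fp_candidates(ppv_pct, tp, n_controls)]
        if not pairs:
            raise NoSolutionError(
                f"no integer (TP, FP) reproduces {model} summary "
                f"Se={sens_pct} PPV={ppv_pct} at totals {reference_totals}",
                constraint=model)
        per_model[model] = pairs

    a, e = final_model_table.tp, final_model_table.fp
    solutions = []
    for (tp1, fp1), (tp2, fp2) in itertools.product(per_model["model1"],
                                                    per_model["model2"]):
        b, c = tp1 - a, tp2 - a            # case dx-only / proc-only
        f, g = fp1 - e, fp2 - e            # control dx-only / proc-only
        d = n_cases - a - b - c
        h = n_controls - e - f - g
        if min(b, c, d, f, g, h) < 0:
            continue
        solutions.append(JointCountFixture(
            StratumCounts(a, b, c, d), StratumCounts(e, f, g, h)))
    if not solutions:
        raise NoSolutionError(
            "per-model summaries are incompatible with the final model table",
            constraint="joint")
    if len(set(solutions)) > 1:
        raise NoSolutionError(
            f"{len(set(solutions))} distinct joint-count solutions; "
            "summaries underdetermine the fixture", constraint="uniqueness")
    return solutions[0]


def derivation_fixture() -> JointCountFixture:
    """The solved joint-count fixture of the published derivation cohort."""
    fx = solve_joint_counts(
        published.MODEL_SUMMARIES,
        (published.DERIVATION_CASES, published.DERIVATION_CONTROLS),
        published.DERIVATION_TABLE,
    )
    return JointCountFixture(fx.cases, fx.controls, year_label="2011-2012")


def validation_year_fixture() -> JointCountFixture:
    """Fixture for the sampled internal-validation cohort (392 encounters).

    All 192 model-predicted cases carry both codes; the 2 false-negative
    cases sit in the dx-only stratum (CRS diagnosis coded but no ESS
    procedure code) among the 200 sampled predicted controls.
    """
    t = published.VALIDATION_TABLE
    return JointCountFixture(
        cases=StratumCounts(both=t.tp, dx_only=t.fn, proc_only=0, neither=0),
        controls=StratumCounts(both=t.fp, dx_only=0, proc_only=0, neither=t.tn),
        year_label="2013",
    )


# -- realization --------------------------------------------------------

# Concrete child-rubric diagnosis codes drawn for "dx present" encounters.
_DX_POOL = ["J320", "J321", "J322", "J323", "J324", "J328", "J329",
            "J330", "J331", "J338", "J339"]
# Qualifier alphabet used to complete CCI wildcard patterns.
_QUALIFIER_ALPHABET = "ABCDEFGHJKLMNPQRSTUVWXZ"
# Filler codes for absent strata: common non-sinus diagnoses and
# non-sinus CCI procedures (verified non-matching at import of tests).
_DX_FILLER = ["I109", "K219", "E119", "M545", "N390", "C509", "K409"]
_PROC_FILLER = ["1AA35HAC1", "1OT53LA", "2GY71BA", "1VG53LA", "1SQ53JA"]


def _proc_pool() -> list[str]:
    pool = []
    for p in get_code_list(ESS_CCI).patterns:
        pool.append(p.wildcard_prefix)
    return pool


def _year_dates(year_label: str) -> tuple[_dt.date, int]:
    try:
        year = int(year_label.split("-")[0])
    except (ValueError, IndexError):
        year = 2011
    start = _dt.date(year, 1, 1)
    return start, 365


def realize_cohort(fixture: JointCountFixture, seed: int) -> list[Encounter]:
    """Emit one encounter per fixture count, with concrete codes.

    "dx present" encounters receive one concrete CRS ICD-10 child code
    drawn uniformly; "proc present" encounters one concrete completion of
    an ESS CCI wildcard pattern; absent slots receive non-matching filler
    codes so controls still carry realistic coded content. Reference
    labels come from the stratum. Row order is shuffled by the seed; the
    implied model confusion tables do not depend on the seed.
    """
    rng = np.random.default_rng(seed)
    proc_pool = _proc_pool()
    start, span = _year_dates(fixture.year_label)

    spec: list[tuple[str, bool, bool, int]] = []
    for label, counts in ((CASE, fixture.cases), (CONTROL, fixture.controls)):
        spec.append((label, True, True, counts.both))
        spec.append((label, True, False, counts.dx_only))
        spec.append((label, False, True, counts.proc_only))
        spec.append((label, False, False, counts.neither))

    n = fixture.total
    encounters: list[Encounter] = []
    idx = 0
    for label, has_dx, has_proc, count in spec:
        if count == 0:
            continue
        dx_pick = rng.integers(0, len(_DX_POOL), size=count)
        dxf_pick = rng.integers(0, len(_DX_FILLER), size=count)
        proc_pick = rng.integers(0, len(proc_pool), size=count)
        procf_pick = rng.integers(0, len(_PROC_FILLER), size=count)
        qual = rng.integers(0, len(_QUALIFIER_ALPHABET), size=(count, 2))
        ages = rng.integers(18, 91, size=count)
        day = rng.integers(0, span, size=count)
        for i in range(count):
            if has_dx:
                dx = frozenset((_DX_POOL[dx_pick[i]],))
            else:
                dx = frozenset((_DX_FILLER[dxf_pick[i]],))
            if has_proc:
                q = (_QUALIFIER_ALPHABET[qual[i, 0]] +
                     _QUALIFIER_ALPHABET[qual[i, 1]])
                proc = frozenset((proc_pool[proc_pick[i]] + q,))
            else:
                proc = frozenset((_PROC_FILLER[procf_pick[i]],))
            encounters.append(Encounter(
                encounter_id=f"E{idx:07d}",
                patient_id=f"P{idx:07d}",
                age=int(ages[i]),
                date=start + _dt.timedelta(days=int(day[i])),
                dx_codes=dx,
                proc_codes=proc,
                reference_label=label,
            ))
            idx += 1
    order = rng.permutation(n)
    return [encounters[i] for i in order]


@dataclass(frozen=True)
class GeneratorParams:
    """Free parameters for parametric cohort generation.

    ``dependence`` is the within-stratum correlation (phi coefficient)
    between diagnosis-code and procedure-code presence; 0 means
    independent draws.
    """

    n_cases: int
    n_controls: int
    p_dx_given_case: float
    p_proc_given_case: float
    p_dx_given_control: float
    p_proc_given_control: float
    seed: int
    dependence: float = 0.0

    def __post_init__(self) -> None:
        if self.n_cases < 0 or self.n_controls < 0:
            raise InputError("cohort sizes must be >= 0")
        for name in ("p_dx_given_case", "p_proc_given_case",
                     "p_dx_given_control", "p_proc_given_control"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise InputError(f"{name} must be in [0, 1], got {v}")
        if not -1 <= self.dependence <= 1:
            raise InputError("dependence must be in [-1, 1]")


def _joint_cell_probs(p1: float, p2: float, phi: float) -> np.ndarray:
    """Cell probabilities (both, dx_only, proc_only, neither) for two
    Bernoullis with marginals p1, p2 and phi correlation, clipped to the
    Frechet feasibility bounds."""
    cov = phi * np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))
    p11 = p1 * p2 + cov
    p11 = min(max(p11, max(0.0, p1 + p2 - 1)), min(p1, p2))
    return np.array([p11, p1 - p11, p2 - p11, 1 - p1 - p2 + p11])


def parametric_generate(params: GeneratorParams) -> list[Encounter]:
    """Draw a cohort with per-stratum code-presence probabilities.

    Deterministic for a fixed seed. Realization of concrete codes reuses
    the fixture machinery, so labels depend only on presence draws.
    """
    rng = np.random.default_rng(params.seed)
    case_cells = rng.multinomial(params.n_cases, _joint_cell_probs(
        params.p_dx_given_case, params.p_proc_given_case, params.dependence))
    ctrl_cells = rng.multinomial(params.n_controls, _joint_cell_probs(
        params.p_dx_given_control, params.p_proc_given_control,
        params.dependence))
    fixture = JointCountFixture(
        cases=StratumCounts(*map(int, case_cells)),
        controls=StratumCounts(*map(int, ctrl_cells)),
        year_label="parametric",
    )
    return realize_cohort(fixture, seed=int(rng.integers(0, 2**31 - 1)))


def sample_validation_cohort(cohort: Sequence[Encounter],
                             algorithm: PhenotypeAlgorithm | str,
                             n_controls: int, seed: int) -> list[Encounter]:
    """Internal-validation sampling: all predicted cases plus a seeded
    uniform sample (without replacement) of ``n_controls`` predicted
    controls."""
    cohort = list(cohort)
    labels = apply_algorithm(cohort, algorithm)
    pred_cases = [e for e, l in zip(cohort, labels) if l.label == CASE]
    pred_controls = [e for e, l in zip(cohort, labels) if l.label == CONTROL]
    if n_controls > len(pred_controls):
        raise InputError(
            f"requested {n_controls} controls but only "
            f"{len(pred_controls)} model-identified controls available")
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(pred_controls), size=n_controls, replace=False)
    return pred_cases + [pred_controls[i] for i in sorted(pick)]


def apply_attrition(cohort: Sequence[Encounter], n_lost_cases: int,
                    n_lost_controls: int, seed: int) -> list[Encounter]:
    """Remove a seeded random subset per reference stratum (emulating
    record-linkage losses)."""
    cohort = list(cohort)
    rng = np.random.default_rng(seed)
    drop: set[str] = set()
    for label, n_lost in ((CASE, n_lost_cases), (CONTROL, n_lost_controls)):
        ids = [e.encounter_id for e in cohort if e.reference_label == label]
        if n_lost > len(ids):
            raise InputError(
                f"cannot remove {n_lost} {label}(s); only {len(ids)} present")
        if n_lost:
            drop.update(rng.choice(ids, size=n_lost, replace=False))
    return [e for e in cohort if e.encounter_id not in drop]
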