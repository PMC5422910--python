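"""Phenotype algorithms over coded surgical encounters.

A phenotype algorithm is a boolean combination (ALL or ANY) of clauses,
each clause asking whether an encounter's diagnostic or procedural code
set contains at least one code from a named code list. Three standard
model variants identify encounters in which endoscopic sinus surgery
(ESS) was performed for chronic rhinosinusitis (CRS):

* ``model1`` — any CRS ICD-10 diagnostic code;
* ``model2`` — any ESS CCI procedural code;
* ``model3`` — both (the final, validated model).

Every encounter an algorithm does not label a case is a control.

The scikit-learn facing surface is :class:`PhenotypeClassifier`; the
module-level functions (:func:`classify_encounter`, :func:`apply_algorithm`)
are thin wrappers over it.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .errors import ConfigurationError, InputError
from .matching import (
    CRS_ICD10,
    ESS_CCI,
    CodeList,
    CodeSystem,
    any_match,
    get_code_list,
    normalize_code,
)

__all__ = [
    "Encounter",
    "Clause",
    "PhenotypeAlgorithm",
    "PredictedLabel",
    "PhenotypeClassifier",
    "model_catalog",
    "classify_encounter",
    "apply_algorithm",
    "filter_adults",
    "load_algorithm",
]

logger = logging.getLogger(__name__)

CASE = "case"
CONTROL = "control"
UNKNOWN = "unknown"


@dataclass(frozen=True, slots=True)
class Encounter:
    """One surgical encounter with its coded diagnoses and procedures.

    ``dx_codes`` and ``proc_codes`` hold canonical (dotless, uppercase)
    codes and may be empty. ``reference_label`` is the chart-review ground
    truth: ``case``, ``control`` or ``unknown`` when unlabelled.
    """

    encounter_id: str
    patient_id: str = ""
    age: int | None = None
    date: _dt.date | None = None
    dx_codes: frozenset[str] = frozenset()
    proc_codes: frozenset[str] = frozenset()
    reference_label: str = UNKNOWN

    def __post_init__(self) -> None:
        if self.reference_label not in (CASE, CONTROL, UNKNOWN):
            raise InputError(
                f"bad reference label {self.reference_label!r} on "
                f"encounter {self.encounter_id!r}"
            )
        object.__setattr__(self, "dx_codes", frozenset(self.dx_codes))
        object.__setattr__(self, "proc_codes", frozenset(self.proc_codes))

    @classmethod
    def from_raw_codes(cls, encounter_id: str, dx: Iterable[str] = (),
                       proc: Iterable[str] = (), **kwargs) -> "Encounter":
        """Build an encounter, normalizing raw (possibly dotted) codes."""
        return cls(
            encounter_id,
            dx_codes=frozenset(normalize_code(c) for c in dx),
            proc_codes=frozenset(normalize_code(c) for c in proc),
            **kwargs,
        )

    def codes(self, which: str) -> frozenset[str]:
        return self.dx_codes if which == "dx" else self.proc_codes


@dataclass(frozen=True)
class Clause:
    """One condition: the encounter's dx or proc codes hit a code list."""

    field: Literal["dx", "proc"]
    code_list: CodeList

    def __post_init__(self) -> None:
        if self.field not in ("dx", "proc"):
            raise ConfigurationError(f"bad clause field {self.field!r}")
        is_proc_system = self.code_list.system is CodeSystem.CCI
        if (self.field == "proc") != is_proc_system:
            raise ConfigurationError(
                f"clause field {self.field!r} is incompatible with code "
                f"system {self.code_list.system.value}"
            )

    def satisfied_by(self, encounter: Encounter) -> bool:
        return any_match(self.code_list, encounter.codes(self.field))


@dataclass(frozen=True)
class PhenotypeAlgorithm:
    """A named ALL/ANY combination of code-list clauses."""

    name: str
    combiner: Literal["ALL", "ANY"]
    clauses: tuple[Clause, ...]

    def __post_init__(self) -> None:
        if self.combiner not in ("ALL", "ANY"):
            raise ConfigurationError(f"bad combiner {self.combiner!r}")
        if not self.clauses:
            raise ConfigurationError("algorithm needs at least one clause")
        object.__setattr__(self, "clauses", tuple(self.clauses))

    def is_case(self, encounter: Encounter) -> bool:
        hits = (c.satisfied_by(encounter) for c in self.clauses)
        return all(hits) if self.combiner == "ALL" else any(hits)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "combiner": self.combiner,
            "clauses": [
                {"field": c.field, "code_list": c.code_list.name}
                for c in self.clauses
            ],
        }

    @classmethod
    def from_dict(cls, d: dict, code_lists: Sequence[CodeList] = ()) -> "PhenotypeAlgorithm":
        clauses = tuple(
            Clause(c["field"], get_code_list(c["code_list"], code_lists))
            for c in d["clauses"]
        )
        return cls(d["name"], d["combiner"], clauses)


@dataclass(frozen=True, slots=True)
class PredictedLabel:
    encounter_id: str
    label: str  # case | control


def model_catalog() -> dict[str, PhenotypeAlgorithm]:
    """The three standard ESS-CRS model variants, keyed by name."""
    dx_clause = Clause("dx", get_code_list(CRS_ICD10))
    proc_clause = Clause("proc", get_code_list(ESS_CCI))
    return {
        "model1": PhenotypeAlgorithm("model1", "ANY", (dx_clause,)),
        "model2": PhenotypeAlgorithm("model2", "ANY", (proc_clause,)),
        "model3": PhenotypeAlgorithm("model3", "ALL", (dx_clause, proc_clause)),
    }


def resolve_algorithm(algorithm: PhenotypeAlgorithm | str,
                      code_lists: Sequence[CodeList] = ()) -> PhenotypeAlgorithm:
    """Accept an algorithm object, a catalog name, or a JSON file path."""
    if isinstance(algorithm, PhenotypeAlgorithm):
        return algorithm
    catalog = model_catalog()
    if algorithm in catalog:
        return catalog[algorithm]
    path = Path(algorithm)
    if path.suffix.lower() == ".json" and path.exists():
        return load_algorithm(path, code_lists)
    raise ConfigurationError(f"unknown algorithm: {algorithm!r}")


def load_algorithm(path: str | Path, code_lists: Sequence[CodeList] = ()) -> PhenotypeAlgorithm:
    """Load an algorithm from JSON.

    The document may carry its own ``code_lists`` definitions next to the
    ``algorithm``; otherwise clause names resolve against the built-ins.
    """
    doc = json.loads(Path(path).read_text())
    if "algorithm" in doc:
        extra = tuple(CodeList.from_dict(d) for d in doc.get("code_lists", []))
        return PhenotypeAlgorithm.from_dict(doc["algorithm"], tuple(code_lists) + extra)
    return PhenotypeAlgorithm.from_dict(doc, code_lists)


class PhenotypeClassifier(BaseEstimator, ClassifierMixin):
    """Rule-based encounter classifier applying a phenotype algorithm.

    The estimator is deterministic and needs no training data: ``fit``
    validates the cohort and resolves the algorithm; ``predict`` labels
    each encounter ``case`` or ``control``. It accepts either a sequence
    of :class:`Encounter` or a DataFrame with ``dx_codes`` / ``proc_codes``
    columns (";"-separated raw codes or iterables of codes).

    Parameters
    ----------
    algorithm : str or PhenotypeAlgorithm, default "model3"
        A catalog name (``model1``/``model2``/``model3``), an algorithm
        object, or a path to an algorithm JSON file.
    min_age : int or None, default None
        If set, encounters below this age are labelled ``control``
        regardless of codes (cohort-inclusion style filtering at predict
        time is usually better done with :func:`filter_adults`).
    """

    def __init__(self, algorithm: PhenotypeAlgorithm | str = "model3",
                 min_age: int | None = None):
        self.algorithm = algorithm
        self.min_age = min_age

    def fit(self, X, y=None) -> "PhenotypeClassifier":
        self.algorithm_ = resolve_algorithm(self.algorithm)
        self.classes_ = np.array([CASE, CONTROL])
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "algorithm_"):
            raise ConfigurationError("classifier is not fitted; call fit first")

    def predict(self, X) -> np.ndarray:
        """Label each encounter; returns an array of 'case'/'control'."""
        self._check_fitted()
        encounters = as_encounters(X)
        _check_unique_ids(encounters)
        out = []
        for e in encounters:
            if self.min_age is not None and e.age is not None and e.age < self.min_age:
                out.append(CONTROL)
            else:
                out.append(CASE if self.algorithm_.is_case(e) else CONTROL)
        return np.asarray(out, dtype=object)

    def predict_labels(self, X) -> list[PredictedLabel]:
        encounters = as_encounters(X)
        labels = self.predict(encounters)
        return [PredictedLabel(e.encounter_id, l) for e, l in zip(encounters, labels)]

    def score(self, X, y) -> float:
        """Accuracy against reference labels."""
        return float(np.mean(self.predict(X) == np.asarray(y)))


def _split_codes(cell) -> frozenset[str]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return frozenset()
    if isinstance(cell, str):
        parts = [p for p in cell.split(";") if p.strip()]
    else:
        parts = list(cell)
    return frozenset(normalize_code(p) for p in parts)


def as_encounters(X) -> list[Encounter]:
    """Coerce a cohort (Encounter sequence or DataFrame) to encounters."""
    if isinstance(X, pd.DataFrame):
        encs = []
        for row in X.itertuples(index=False):
            d = row._asdict()
            age = d.get("age")
            if age is not None and not pd.isna(age):
                age = int(age)
            else:
                age = None
            date = d.get("date")
            if date is None or (isinstance(date, float) and np.isnan(date)) or date == "":
                date = None
            elif isinstance(date, str):
                date = _dt.date.fromisoformat(date)
            elif isinstance(date, pd.Timestamp):
                date = date.date()
            label = d.get("reference_label", UNKNOWN)
            if label is None or (isinstance(label, float) and np.isnan(label)) or label == "":
                label = UNKNOWN
            encs.append(Encounter(
                encounter_id=str(d["encounter_id"]),
                patient_id=str(d.get("patient_id", "")),
                age=age,
                date=date,
                dx_codes=_split_codes(d.get("dx_codes")),
                proc_codes=_split_codes(d.get("proc_codes")),
                reference_label=str(label),
            ))
        return encs
    return list(X)


def _check_unique_ids(encounters: Sequence[Encounter]) -> None:
    ids = [e.encounter_id for e in encounters]
    if len(set(ids)) != len(ids):
        seen, dup = set(), None
        for i in ids:
            if i in seen:
                dup = i
                break
            seen.add(i)
        raise InputError(f"duplicate encounter id: {dup!r}")


def classify_encounter(encounter: Encounter,
                       algorithm: PhenotypeAlgorithm | str) -> PredictedLabel:
    """Label a single encounter under an algorithm (pure, deterministic)."""
    clf = PhenotypeClassifier(algorithm=algorithm).fit(None)
    return clf.predict_labels([encounter])[0]


def apply_algorithm(cohort: Iterable[Encounter],
                    algorithm: PhenotypeAlgorithm | str) -> list[PredictedLabel]:
    """Label every encounter in a cohort, preserving order.

    Raises
    ------
    InputError
        If encounter ids are not unique within the cohort.
    """
    clf = PhenotypeClassifier(algorithm=algorithm).fit(None)
    return clf.predict_labels(cohort)


def filter_adults(cohort: Iterable[Encounter], min_age: int = 18) -> list[Encounter]:
    """Retain encounters with age >= ``min_age``.

    Encounters with missing age are retained (the age rule is a cohort
    inclusion criterion, not part of the coded model) with a logged
    warning so attrition stays auditable.
    """
    if min_age < 0:
        raise ConfigurationError("min_age must be >= 0")
    kept = []
    n_missing = 0
    for e in cohort:
        if e.age is None:
            n_missing += 1
            kept.append(e)
        elif e.age >= min_age:
            kept.append(e)
    if n_missing:
        logger.warning("retained %d encounter(s) with missing age", n_missing)
    return kept
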