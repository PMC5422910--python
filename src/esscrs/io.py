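"""Reading and writing encounter cohorts and predictions.

Encounter CSV dialect: header row with columns ``encounter_id,
patient_id, age, date, dx_codes, proc_codes, reference_label``; code
columns are ";"-separated raw codes (normalized on read), dates are
ISO-8601, an empty reference label means unlabelled. UTF-8 throughout.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import InputError
from .phenotype import UNKNOWN, Encounter, PredictedLabel

__all__ = ["read_encounters_csv", "write_encounters_csv",
           "cohort_to_frame", "write_predictions_csv"]

COLUMNS = ["encounter_id", "patient_id", "age", "date",
           "dx_codes", "proc_codes", "reference_label"]


def cohort_to_frame(cohort: Iterable[Encounter]) -> pd.DataFrame:
    """Render encounters in the CSV column layout (raw-compatible)."""
    rows = []
    for e in cohort:
        rows.append({
            "encounter_id": e.encounter_id,
            "patient_id": e.patient_id,
            "age": e.age if e.age is not None else "",
            "date": e.date.isoformat() if e.date else "",
            "dx_codes": ";".join(sorted(e.dx_codes)),
            "proc_codes": ";".join(sorted(e.proc_codes)),
            "reference_label": "" if e.reference_label == UNKNOWN
                               else e.reference_label,
        })
    return pd.DataFrame(rows, columns=COLUMNS)


def write_encounters_csv(cohort: Iterable[Encounter], path: str | Path) -> None:
    cohort_to_frame(cohort).to_csv(path, index=False)


def read_encounters_csv(path: str | Path) -> list[Encounter]:
    """Load a cohort, normalizing codes; raises InputError with the
    offending line number on malformed rows."""
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except (pd.errors.ParserError, OSError) as exc:
        raise InputError(f"cannot read {path}: {exc}") from exc
    missing = [c for c in ("encounter_id", "dx_codes", "proc_codes")
               if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing required column(s) {missing}")
    encounters = []
    for i, row in enumerate(df.to_dict("records")):
        try:
            encounters.append(_row_to_encounter(row))
        except (InputError, ValueError) as exc:
            raise InputError(f"{path}: line {i + 2}: {exc}") from exc
    ids = [e.encounter_id for e in encounters]
    if len(set(ids)) != len(ids):
        raise InputError(f"{path}: duplicate encounter ids")
    return encounters


def _row_to_encounter(row: dict) -> Encounter:
    import datetime as _dt

    from .matching import normalize_code

    age = row.get("age", "")
    date = row.get("date", "")
    label = row.get("reference_label", "") or UNKNOWN
    return Encounter(
        encounter_id=row["encounter_id"],
        patient_id=row.get("patient_id", ""),
        age=int(age) if age != "" else None,
        date=_dt.date.fromisoformat(date) if date != "" else None,
        dx_codes=frozenset(normalize_code(c)
                           for c in row["dx_codes"].split(";") if c.strip()),
        proc_codes=frozenset(normalize_code(c)
                             for c in row["proc_codes"].split(";") if c.strip()),
        reference_label=label,
    )


def write_predictions_csv(labels: Sequence[PredictedLabel],
                          path: str | Path) -> None:
    pd.DataFrame(
        [{"encounter_id": l.encounter_id, "predicted_label": l.label}
         for l in labels],
        columns=["encounter_id", "predicted_label"],
    ).to_csv(path, index=False)
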