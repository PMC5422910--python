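"""Administrative code systems and code-list matching.

Diagnostic codes (ICD-10-CA, ICD-9) and procedural codes (CCI, the Canadian
Classification of Health Interventions) are carried as short alphanumeric
strings. Published code lists print them with dot separators ("J32.0",
"1.EU.52.^^") while stored data dialects usually drop the dots, so every
code is normalized to a canonical dotless uppercase form before matching.

Matching is hierarchical: a pattern matches any code that extends it
("J32" matches "J324"), which makes a list robust to whether the source
data coded the parent rubric or a child. CCI wildcard groups ("^^") mark
qualifier fields that may take any value; a wildcard pattern matches every
code sharing the text before the first wildcard group.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from .errors import ConfigurationError, InvalidCodeError

__all__ = [
    "CodeSystem",
    "CodePattern",
    "CodeList",
    "normalize_code",
    "code_matches",
    "any_match",
    "builtin_code_lists",
    "get_code_list",
]


class CodeSystem(str, Enum):
    """The three coding systems used in Canadian hospital claims data."""

    ICD10 = "ICD10"
    ICD9 = "ICD9"
    CCI = "CCI"


WILDCARD = "^^"


def normalize_code(raw: str, system: CodeSystem | str | None = None) -> str:
    """Canonicalize a raw code: uppercase, strip dots and whitespace.

    Wildcard groups (``^^``) are preserved. The ``system`` argument is
    accepted for interface symmetry; normalization rules are identical
    across the three systems.

    Raises
    ------
    InvalidCodeError
        If the code is empty after trimming.
    """
    canonical = "".join(raw.split()).replace(".", "").upper()
    if not canonical:
        raise InvalidCodeError(f"empty code after normalization: {raw!r}")
    return canonical


@dataclass(frozen=True)
class CodePattern:
    """One normalized code or wildcard prefix in a named coding system.

    ``canonical`` is the dotless uppercase form; ``wildcard_prefix`` is the
    canonical text before the first wildcard group (equal to ``canonical``
    for non-wildcard patterns).
    """

    system: CodeSystem
    raw: str
    canonical: str = field(init=False, compare=False)
    wildcard_prefix: str = field(init=False, compare=False)
    is_wildcard: bool = field(init=False, compare=False)

    def __post_init__(self) -> None:
        canonical = normalize_code(self.raw, self.system)
        object.__setattr__(self, "canonical", canonical)
        object.__setattr__(self, "is_wildcard", WILDCARD in canonical)
        prefix = canonical.split("^", 1)[0]
        object.__setattr__(self, "wildcard_prefix", prefix)

    def matches(self, code: str) -> bool:
        """Hierarchical prefix match against a canonical code."""
        return code.startswith(self.wildcard_prefix)


def code_matches(pattern: CodePattern, code: str) -> bool:
    """True iff ``code`` (canonical) falls under ``pattern``.

    Non-wildcard patterns match any code they prefix (parent rubric rule);
    wildcard patterns match any code extending the text before the first
    wildcard group.
    """
    return pattern.matches(code)


@dataclass(frozen=True)
class CodeList:
    """A named, deduplicated, ordered collection of patterns in one system."""

    name: str
    system: CodeSystem
    patterns: tuple[CodePattern, ...]

    def __post_init__(self) -> None:
        for p in self.patterns:
            if p.system is not self.system:
                raise ConfigurationError(
                    f"code list {self.name!r} is {self.system.value} but "
                    f"pattern {p.raw!r} is {p.system.value}"
                )
        seen: set[str] = set()
        deduped = []
        for p in self.patterns:
            key = p.canonical
            if key not in seen:
                seen.add(key)
                deduped.append(p)
        object.__setattr__(self, "patterns", tuple(deduped))

    @classmethod
    def from_raw(cls, name: str, system: CodeSystem | str, codes: Iterable[str]) -> "CodeList":
        system = CodeSystem(system)
        return cls(name, system, tuple(CodePattern(system, c) for c in codes))

    def matches(self, codes: Iterable[str]) -> bool:
        return any_match(self, codes)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "system": self.system.value,
            "codes": [p.raw for p in self.patterns],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CodeList":
        return cls.from_raw(d["name"], d["system"], d["codes"])

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CodeList":
        return cls.from_dict(json.loads(Path(path).read_text()))


def any_match(code_list: CodeList, codes: Iterable[str]) -> bool:
    """True iff some pattern in the list matches some canonical code."""
    codes = tuple(codes)
    return any(p.matches(c) for c in codes for p in code_list.patterns)


# Published code lists for the ESS-CRS phenotype. ICD-10 carries chronic
# sinusitis (J32 family) and nasal polyposis (J33 family); CCI carries
# therapeutic interventions on the ethmoidal (1.EU), sphenoidal (1.EV),
# maxillary (1.EW), frontal (1.EX) and paranasal (1.EY) sinuses. The ICD-9
# list is the historical analogue, carried as data only. Rows duplicated
# in the published table are stored once (set semantics).
_CRS_ICD10 = [
    "J32", "J32.0", "J32.1", "J32.2", "J32.3", "J32.4", "J32.8", "J32.9",
    "J33", "J33.0", "J33.1", "J33.8", "J33.9",
]
_CRS_ICD9 = [
    "473", "473.0", "473.1", "473.2", "473.3", "473.8", "473.9",
    "471", "471.0", "471.1", "471.8", "471.9",
]
_ESS_CCI = [
    "1.EU.^^.^^", "1.EU.52.^^", "1.EU.87.^^",
    "1.EV.^^.^^", "1.EV.52.^^", "1.EV.87.^^",
    "1.EW.^^.^^", "1.EW.52.^^",
    "1.EX.^^", "1.EX.52.^^", "1.EX.59.^^", "1.EX.80.^^", "1.EX.87.^^",
    "1.EY.^^.^^", "1.EY.87.^^", "1.EY.91.^^",
]

CRS_ICD10 = "crs_icd10"
CRS_ICD9 = "crs_icd9"
ESS_CCI = "ess_cci"


def builtin_code_lists() -> tuple[CodeList, CodeList, CodeList]:
    """The three built-in code lists: CRS ICD-10, CRS ICD-9, ESS CCI."""
    return (
        CodeList.from_raw(CRS_ICD10, CodeSystem.ICD10, _CRS_ICD10),
        CodeList.from_raw(CRS_ICD9, CodeSystem.ICD9, _CRS_ICD9),
        CodeList.from_raw(ESS_CCI, CodeSystem.CCI, _ESS_CCI),
    )


def get_code_list(name: str, extra: Sequence[CodeList] = ()) -> CodeList:
    """Resolve a code list by name from built-ins plus optional extras."""
    for cl in tuple(extra) + builtin_code_lists():
        if cl.name == name:
            return cl
    raise ConfigurationError(f"unknown code list: {name!r}")
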