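"""Clinical code lists driving phenotyping and covariate derivation.

A code list is a flat delimited-text table of clinical codes (Read and
SNOMED CT for primary care, ICD-10 for the specialist source) annotated
with the semantics the pipeline needs: a *domain* (dementia, comorbidity,
smoking, medication, ethnicity), a *specificity* tier for dementia codes
(high-specificity codes indicate dementia on their own; low-specificity
codes require a second, different low-specificity code), a dementia
*subtype* tag, a Charlson comorbidity condition name and weight, a smoking
state tag and a drug class.

Matching downstream is exact, case-sensitive string matching on
``(terminology, code)``; there is no hierarchy expansion and no
terminology mapping — both Read and SNOMED dementia codes appear as
independent rows of the same list.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Optional


class Terminology(str, Enum):
    READ = "READ"
    SNOMED = "SNOMED"
    ICD10 = "ICD10"


class Domain(str, Enum):
    DEMENTIA = "DEMENTIA"
    COMORBIDITY = "COMORBIDITY"
    SMOKING = "SMOKING"
    MEDICATION = "MEDICATION"
    ETHNICITY = "ETHNICITY"


class Specificity(str, Enum):
    HIGH = "HIGH"
    LOW = "LOW"
    NA = "NA"


class SubtypeTag(str, Enum):
    ALZHEIMERS_MIXED = "ALZHEIMERS_MIXED"
    VASCULAR = "VASCULAR"
    OTHER_SPECIFIED = "OTHER_SPECIFIED"
    UNSPECIFIED = "UNSPECIFIED"
    NONE = "NONE"


class SmokingTag(str, Enum):
    CURRENT = "CURRENT"
    NEVER = "NEVER"
    FORMER = "FORMER"
    NONE = "NONE"


class DrugClass(str, Enum):
    ACHEI = "ACHEI"
    MEMANTINE = "MEMANTINE"
    NONE = "NONE"


COLUMNS = [
    "terminology",
    "code",
    "term",
    "domain",
    "specificity",
    "subtype_tag",
    "condition",
    "weight",
    "smoking_tag",
    "drug_class",
]


class CodeListError(ValueError):
    """Raised on a malformed or invariant-violating code list."""


@dataclass(frozen=True)
class CodeEntry:
    """One clinical code with its phenotyping semantics."""

    terminology: Terminology
    code: str
    term: str
    domain: Domain
    specificity: Specificity = Specificity.NA
    subtype_tag: SubtypeTag = SubtypeTag.NONE
    condition: str = ""
    weight: int = 0
    smoking_tag: SmokingTag = SmokingTag.NONE
    drug_class: DrugClass = DrugClass.NONE

    def validate(self) -> None:
        if (self.specificity in (Specificity.HIGH, Specificity.LOW)) != (
            self.domain is Domain.DEMENTIA
        ):
            raise CodeListError(
                f"({self.terminology.value},{self.code}): specificity must be "
                "HIGH or LOW exactly when domain is DEMENTIA"
            )
        if self.weight < 0:
            raise CodeListError(
                f"({self.terminology.value},{self.code}): negative Charlson weight"
            )
        if self.weight > 0 and (
            self.domain is not Domain.COMORBIDITY or not self.condition
        ):
            raise CodeListError(
                f"({self.terminology.value},{self.code}): weight > 0 requires "
                "domain COMORBIDITY and a nonempty condition"
            )
        if self.domain is Domain.COMORBIDITY and self.condition.strip().lower() == "dementia":
            # modified Charlson index: dementia itself is excluded
            raise CodeListError(
                f"({self.terminology.value},{self.code}): COMORBIDITY entries "
                "may not carry condition 'dementia'"
            )


@dataclass
class CodeList:
    """A validated collection of :class:`CodeEntry`, keyed by (terminology, code)."""

    entries: list[CodeEntry]
    name: str = "codelist"
    version: str = "0"
    _index: dict[tuple[Terminology, str], CodeEntry] = field(
        init=False, repr=False, default_factory=dict
    )

    def __post_init__(self) -> None:
        for i, e in enumerate(self.entries):
            e.validate()
            key = (e.terminology, e.code)
            if key in self._index:
                raise CodeListError(
                    f"row {i + 1}: duplicate ({e.terminology.value},{e.code})"
                )
            self._index[key] = e

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[CodeEntry]:
        return iter(self.entries)

    def lookup(self, terminology: Terminology, code: str) -> Optional[CodeEntry]:
        """Exact, case-sensitive lookup; ``None`` when the code is not listed."""
        return self._index.get((Terminology(terminology), code))

    def subset(self, domain: Domain) -> list[CodeEntry]:
        return [e for e in self.entries if e.domain is domain]

    def condition_weights(self) -> dict[str, int]:
        """Charlson weight per distinct comorbidity condition (max over codes)."""
        out: dict[str, int] = {}
        for e in self.subset(Domain.COMORBIDITY):
            out[e.condition] = max(out.get(e.condition, 0), e.weight)
        return out


def _parse_row(row: dict[str, str], rownum: int) -> CodeEntry:
    def enum(cls, raw, default=None):
        raw = (raw or "").strip()
        if not raw and default is not None:
            return default
        try:
            return cls(raw)
        except ValueError:
            raise CodeListError(
                f"row {rownum}: unknown {cls.__name__} value {raw!r}"
            ) from None

    try:
        weight = int(row.get("weight", "0") or 0)
    except ValueError:
        raise CodeListError(f"row {rownum}: weight must be an integer") from None
    return CodeEntry(
        terminology=enum(Terminology, row["terminology"]),
        code=row["code"].strip(),
        term=row.get("term", "").strip(),
        domain=enum(Domain, row["domain"]),
        specificity=enum(Specificity, row.get("specificity"), Specificity.NA),
        subtype_tag=enum(SubtypeTag, row.get("subtype_tag"), SubtypeTag.NONE),
        condition=(row.get("condition") or "").strip(),
        weight=weight,
        smoking_tag=enum(SmokingTag, row.get("smoking_tag"), SmokingTag.NONE),
        drug_class=enum(DrugClass, row.get("drug_class"), DrugClass.NONE),
    )


def load_codelist(path: str | Path, name: str | None = None, version: str = "0") -> CodeList:
    """Load and validate a code list from a CSV file.

    The file must carry one header row with the documented columns
    (``terminology, code, term, domain, specificity, subtype_tag,
    condition, weight, smoking_tag, drug_class``). Any invariant violation
    is fatal and reported with its row number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise CodeListError(f"{path}: missing columns {sorted(missing)}")
        entries = []
        for rownum, row in enumerate(reader, start=2):
            entry = _parse_row(row, rownum)
            try:
                entry.validate()
            except CodeListError as err:
                raise CodeListError(f"{path} row {rownum}: {err}") from None
            entries.append(entry)
    try:
        return CodeList(entries, name=name or path.stem, version=version)
    except CodeListError as err:
        raise CodeListError(f"{path}: {err}") from None


def write_codelist(codelist: CodeList, path: str | Path) -> None:
    """Write a code list back to CSV; loading the result round-trips."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(COLUMNS)
        for e in codelist:
            writer.writerow(
                [
                    e.terminology.value,
                    e.code,
                    e.term,
                    e.domain.value,
                    e.specificity.value,
                    e.subtype_tag.value,
                    e.condition,
                    e.weight,
                    e.smoking_tag.value,
                    e.drug_class.value,
                ]
            )


def build_codelist(rows: Iterable[CodeEntry], name: str = "codelist", version: str = "0") -> CodeList:
    return CodeList(list(rows), name=name, version=version)
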