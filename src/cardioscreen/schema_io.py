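"""Screening-record data model, validation, and CSV/JSON round-tripping.

A :class:`ScreeningRecord` holds one screened article: its identity, the
journal it appeared in, its study type, and the coded response to every item
of the screening instrument (availability statements for materials, data and
analysis scripts; pre-registration and protocol items; conflict-of-interest,
funding and open-access status).

The CSV dialect is deliberately rigid so that files round-trip bit-exactly:
UTF-8, comma-separated, quoted fields, a header of snake_case column names
matching the field names, enum cells holding the UPPER_SNAKE token, booleans
as ``TRUE``/``FALSE``, and aspect subsets serialized as semicolon-joined
tokens in canonical order. Missingness is always an explicit
``NOT_APPLICABLE`` token, never a blank cell, so "not screened" is
distinguishable from "screened, answer no".
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, fields
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

__all__ = [
    "Journal",
    "StudyType",
    "AvailabilityStatement",
    "AccessMode",
    "TriState",
    "PreregStatement",
    "StudyAspect",
    "CoiStatement",
    "FundingStatement",
    "OpenAccess",
    "MATERIALS_EXEMPT_TYPES",
    "ScreeningRecord",
    "RecordSet",
    "SchemaError",
    "TokenError",
    "RecordValidationError",
    "validate_record",
    "read_records",
    "write_records",
    "records_to_json",
]


class Journal(str, Enum):
    """The three screened cardiovascular journals."""

    CIRCULATION = "CIRCULATION"
    EHJ = "EHJ"
    JACC = "JACC"


class StudyType(str, Enum):
    CLINICAL_TRIAL = "CLINICAL_TRIAL"
    CLINICAL_OBSERVATIONAL = "CLINICAL_OBSERVATIONAL"
    CLINICAL_INTERVENTION = "CLINICAL_INTERVENTION"
    CASE_STUDY_OR_SERIES = "CASE_STUDY_OR_SERIES"
    LAB_ANIMAL = "LAB_ANIMAL"
    LAB_CELL_MOLECULAR = "LAB_CELL_MOLECULAR"
    META_ANALYSIS_SYSTEMATIC_REVIEW = "META_ANALYSIS_SYSTEMATIC_REVIEW"
    NONCLINICAL_SECONDARY_DATA = "NONCLINICAL_SECONDARY_DATA"
    NON_EMPIRICAL = "NON_EMPIRICAL"


#: Empirical study types that by their nature have no shareable materials
#: (the two materials items are dropped from their applicable criteria).
MATERIALS_EXEMPT_TYPES = frozenset(
    {StudyType.META_ANALYSIS_SYSTEMATIC_REVIEW, StudyType.NONCLINICAL_SECONDARY_DATA}
)


class AvailabilityStatement(str, Enum):
    """What an article's availability statement says about a resource."""

    YES_AVAILABLE = "YES_AVAILABLE"
    NO_STATEMENT = "NO_STATEMENT"
    STATES_UNAVAILABLE = "STATES_UNAVAILABLE"
    NOT_APPLICABLE = "NOT_APPLICABLE"


class AccessMode(str, Enum):
    """How availability is claimed, when it is claimed at all."""

    REPOSITORY = "REPOSITORY"
    PERSONAL_OR_INSTITUTIONAL_PAGE = "PERSONAL_OR_INSTITUTIONAL_PAGE"
    SUPPLEMENT = "SUPPLEMENT"
    UPON_REQUEST = "UPON_REQUEST"
    NONE = "NONE"


class TriState(str, Enum):
    YES = "YES"
    NO = "NO"
    NOT_APPLICABLE = "NOT_APPLICABLE"


class PreregStatement(str, Enum):
    YES = "YES"
    NO = "NO"


class StudyAspect(str, Enum):
    """Study aspects a pre-registration or protocol may cover."""

    HYPOTHESES = "HYPOTHESES"
    METHODS = "METHODS"
    ANALYSIS_PLAN = "ANALYSIS_PLAN"


#: Canonical serialization order for aspect subsets.
ASPECT_ORDER = (StudyAspect.HYPOTHESES, StudyAspect.METHODS, StudyAspect.ANALYSIS_PLAN)


class CoiStatement(str, Enum):
    HAS_COI = "HAS_COI"
    NO_COI = "NO_COI"
    ABSENT = "ABSENT"


class FundingStatement(str, Enum):
    PRIVATE = "PRIVATE"
    PUBLIC = "PUBLIC"
    BOTH = "BOTH"
    NO_FUNDING = "NO_FUNDING"
    ABSENT = "ABSENT"


class OpenAccess(str, Enum):
    YES_OA_BUTTON = "YES_OA_BUTTON"
    YES_OTHER = "YES_OTHER"
    NO = "NO"


class SchemaError(ValueError):
    """A file does not have the expected column structure."""


class TokenError(ValueError):
    """A cell holds a token outside its controlled vocabulary."""


class RecordValidationError(ValueError):
    """A record violates the instrument's structural invariants."""


@dataclass(frozen=True)
class ScreeningRecord:
    """Coded screening responses for one article."""

    article_id: str
    journal: Journal
    study_type: StudyType
    study_type_stated: bool

    materials_statement: AvailabilityStatement = AvailabilityStatement.NO_STATEMENT
    materials_mode: AccessMode = AccessMode.NONE
    materials_accessible: TriState = TriState.NOT_APPLICABLE

    data_statement: AvailabilityStatement = AvailabilityStatement.NO_STATEMENT
    data_mode: AccessMode = AccessMode.NONE
    data_accessible: TriState = TriState.NOT_APPLICABLE
    data_documented: TriState = TriState.NOT_APPLICABLE
    data_complete: TriState = TriState.NOT_APPLICABLE

    scripts_statement: AvailabilityStatement = AvailabilityStatement.NO_STATEMENT
    scripts_mode: AccessMode = AccessMode.NONE
    scripts_accessible: TriState = TriState.NOT_APPLICABLE

    prereg_statement: PreregStatement = PreregStatement.NO
    prereg_accessible: TriState = TriState.NOT_APPLICABLE
    prereg_aspects: frozenset[StudyAspect] = frozenset()

    protocol_linked: bool = False
    protocol_aspects: frozenset[StudyAspect] = frozenset()

    coi_statement: CoiStatement = CoiStatement.ABSENT
    funding_statement: FundingStatement = FundingStatement.ABSENT
    open_access: OpenAccess = OpenAccess.NO

    country: str | None = None

    @property
    def is_empirical(self) -> bool:
        return self.study_type is not StudyType.NON_EMPIRICAL


@dataclass(frozen=True)
class RecordSet:
    """An ordered, identity-unique collection of screening records."""

    records: tuple[ScreeningRecord, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        seen: set[str] = set()
        for rec in self.records:
            if rec.article_id in seen:
                raise RecordValidationError(
                    f"duplicate article_id {rec.article_id!r} in RecordSet"
                )
            seen.add(rec.article_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def empirical(self) -> tuple[ScreeningRecord, ...]:
        return tuple(r for r in self.records if r.is_empirical)


def _gate_violations(
    prefix: str,
    statement: AvailabilityStatement,
    mode: AccessMode,
    accessible: TriState,
) -> list[str]:
    """Check a statement -> mode/accessible availability chain."""
    out: list[str] = []
    if statement is AvailabilityStatement.YES_AVAILABLE:
        if mode is AccessMode.NONE:
            out.append(
                f"{prefix}_mode: must name a mode when {prefix}_statement is YES_AVAILABLE"
            )
    else:
        if accessible is not TriState.NOT_APPLICABLE:
            out.append(
                f"{prefix}_accessible: must be NOT_APPLICABLE when "
                f"{prefix}_statement is {statement.value}"
            )
        if mode is not AccessMode.NONE:
            out.append(
                f"{prefix}_mode: must be NONE when {prefix}_statement is {statement.value}"
            )
    return out


def validate_record(record: ScreeningRecord) -> list[str]:
    """Return structural-invariant violations (empty list means valid).

    Violations are messages, each starting with the offending field name;
    nothing is raised, so callers can decide between strict and lenient
    handling. The checks are per-field and independent, so the result does
    not depend on any evaluation order.
    """
    v: list[str] = []
    if not record.article_id:
        v.append("article_id: must be nonempty")

    v += _gate_violations(
        "materials",
        record.materials_statement,
        record.materials_mode,
        record.materials_accessible,
    )
    v += _gate_violations(
        "data", record.data_statement, record.data_mode, record.data_accessible
    )
    v += _gate_violations(
        "scripts",
        record.scripts_statement,
        record.scripts_mode,
        record.scripts_accessible,
    )

    # Gated chain below the data-accessibility item.
    if record.data_accessible is not TriState.YES:
        if record.data_documented is not TriState.NOT_APPLICABLE:
            v.append(
                "data_documented: must be NOT_APPLICABLE unless data_accessible is YES"
            )
    if record.data_documented is not TriState.YES:
        if record.data_complete is not TriState.NOT_APPLICABLE:
            v.append(
                "data_complete: must be NOT_APPLICABLE unless data_documented is YES"
            )

    if record.prereg_statement is PreregStatement.NO:
        if record.prereg_accessible is not TriState.NOT_APPLICABLE:
            v.append(
                "prereg_accessible: must be NOT_APPLICABLE when prereg_statement is NO"
            )
    if record.prereg_aspects and record.prereg_accessible is not TriState.YES:
        v.append("prereg_aspects: nonempty only when prereg_accessible is YES")
    if record.protocol_aspects and not record.protocol_linked:
        v.append("protocol_aspects: nonempty only when protocol_linked")

    if record.study_type is StudyType.NON_EMPIRICAL:
        # Non-empirical articles retain coi/funding/open_access only; every
        # accessibility item must sit at its not-applicable default.
        na = AvailabilityStatement.NOT_APPLICABLE
        for name in ("materials_statement", "data_statement", "scripts_statement"):
            if getattr(record, name) is not na:
                v.append(f"{name}: must be NOT_APPLICABLE for NON_EMPIRICAL articles")
        if record.prereg_statement is not PreregStatement.NO:
            v.append("prereg_statement: must be NO for NON_EMPIRICAL articles")
        if record.protocol_linked:
            v.append("protocol_linked: must be false for NON_EMPIRICAL articles")
    elif record.study_type in MATERIALS_EXEMPT_TYPES:
        if record.materials_statement is not AvailabilityStatement.NOT_APPLICABLE:
            v.append(
                "materials_statement: must be NOT_APPLICABLE for study types "
                "without shareable materials"
            )
    return v


# --- CSV serialization ----------------------------------------------------

_ENUM_FIELDS: Mapping[str, type[Enum]] = {
    "journal": Journal,
    "study_type": StudyType,
    "materials_statement": AvailabilityStatement,
    "materials_mode": AccessMode,
    "materials_accessible": TriState,
    "data_statement": AvailabilityStatement,
    "data_mode": AccessMode,
    "data_accessible": TriState,
    "data_documented": TriState,
    "data_complete": TriState,
    "scripts_statement": AvailabilityStatement,
    "scripts_mode": AccessMode,
    "scripts_accessible": TriState,
    "prereg_statement": PreregStatement,
    "prereg_accessible": TriState,
    "coi_statement": CoiStatement,
    "funding_statement": FundingStatement,
    "open_access": OpenAccess,
}
_BOOL_FIELDS = frozenset({"study_type_stated", "protocol_linked"})
_ASPECT_FIELDS = frozenset({"prereg_aspects", "protocol_aspects"})

COLUMNS: tuple[str, ...] = tuple(f.name for f in fields(ScreeningRecord))


def _serialize_cell(name: str, value) -> str:
    if name in _BOOL_FIELDS:
        return "TRUE" if value else "FALSE"
    if name in _ASPECT_FIELDS:
        return ";".join(a.value for a in ASPECT_ORDER if a in value)
    if name == "country":
        return "" if value is None else str(value)
    if isinstance(value, Enum):
        return value.value
    return str(value)


def _parse_cell(name: str, token: str, row_num: int):
    if name in _BOOL_FIELDS:
        if token == "TRUE":
            return True
        if token == "FALSE":
            return False
        raise TokenError(
            f"row {row_num}, column {name!r}: expected TRUE/FALSE, got {token!r}"
        )
    if name in _ASPECT_FIELDS:
        if not token:
            return frozenset()
        try:
            return frozenset(StudyAspect(t) for t in token.split(";"))
        except ValueError:
            raise TokenError(
                f"row {row_num}, column {name!r}: unknown aspect token in {token!r}"
            ) from None
    if name == "country":
        return token or None
    if name in _ENUM_FIELDS:
        try:
            return _ENUM_FIELDS[name](token)
        except ValueError:
            raise TokenError(
                f"row {row_num}, column {name!r}: unknown token {token!r}"
            ) from None
    return token  # article_id


def record_to_row(record: ScreeningRecord) -> dict[str, str]:
    return {name: _serialize_cell(name, getattr(record, name)) for name in COLUMNS}


def write_records(rs: RecordSet, path: str | Path) -> None:
    """Write a RecordSet as canonical CSV; re-reading reproduces it exactly."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=COLUMNS, quoting=csv.QUOTE_ALL)
        writer.writeheader()
        for rec in rs:
            writer.writerow(record_to_row(rec))


def read_records(path: str | Path, strict: bool = True) -> RecordSet:
    """Read screening records from CSV.

    With ``strict=True`` the first malformed or invariant-violating row
    aborts the read; with ``strict=False`` such rows are dropped and the
    kept/dropped counts are logged.
    """
    path = Path(path)
    records: list[ScreeningRecord] = []
    dropped = 0
    with path.open("r", newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        for row_num, row in enumerate(reader, start=2):
            try:
                kwargs = {
                    name: _parse_cell(name, row[name] or "", row_num)
                    for name in COLUMNS
                }
                rec = ScreeningRecord(**kwargs)
                violations = validate_record(rec)
                if violations:
                    raise RecordValidationError(
                        f"row {row_num}: " + "; ".join(violations)
                    )
            except (TokenError, RecordValidationError):
                if strict:
                    raise
                dropped += 1
                continue
            records.append(rec)
    if dropped:
        logger.warning(
            "read_records(%s): dropped %d invalid row(s), kept %d",
            path,
            dropped,
            len(records),
        )
    return RecordSet(records=tuple(records), provenance=str(path))


def records_to_json(rs: RecordSet, indent: int | None = None) -> str:
    """JSON export with the same field names and tokens as the CSV dialect."""
    payload = {
        "provenance": rs.provenance,
        "records": [record_to_row(rec) for rec in rs],
    }
    return json.dumps(payload, indent=indent)
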