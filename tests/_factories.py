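"""Record factories shared across the test modules."""

from __future__ import annotations

from cardioscreen.schema_io import (
    AccessMode,
    AvailabilityStatement,
    CoiStatement,
    FundingStatement,
    Journal,
    OpenAccess,
    PreregStatement,
    RecordSet,
    ScreeningRecord,
    StudyAspect,
    StudyType,
    TriState,
)

ALL_ASPECTS = frozenset(StudyAspect)


def negative_record(article_id: str = "A1", **overrides) -> ScreeningRecord:
    """A valid clinical-trial record with every response negative/absent."""
    base = dict(
        article_id=article_id,
        journal=Journal.CIRCULATION,
        study_type=StudyType.CLINICAL_TRIAL,
        study_type_stated=False,
    )
    base.update(overrides)
    return ScreeningRecord(**base)


def full_record(article_id: str = "A1", **overrides) -> ScreeningRecord:
    """A valid clinical-trial record satisfying all 17 criteria."""
    base = dict(
        article_id=article_id,
        journal=Journal.CIRCULATION,
        study_type=StudyType.CLINICAL_TRIAL,
        study_type_stated=True,
        materials_statement=AvailabilityStatement.YES_AVAILABLE,
        materials_mode=AccessMode.REPOSITORY,
        materials_accessible=TriState.YES,
        data_statement=AvailabilityStatement.YES_AVAILABLE,
        data_mode=AccessMode.REPOSITORY,
        data_accessible=TriState.YES,
        data_documented=TriState.YES,
        data_complete=TriState.YES,
        scripts_statement=AvailabilityStatement.YES_AVAILABLE,
        scripts_mode=AccessMode.REPOSITORY,
        scripts_accessible=TriState.YES,
        prereg_statement=PreregStatement.YES,
        prereg_accessible=TriState.YES,
        prereg_aspects=ALL_ASPECTS,
        protocol_linked=True,
        protocol_aspects=ALL_ASPECTS,
        coi_statement=CoiStatement.HAS_COI,
        funding_statement=FundingStatement.PUBLIC,
        open_access=OpenAccess.YES_OA_BUTTON,
        country="US",
    )
    base.update(overrides)
    return ScreeningRecord(**base)


def non_empirical_record(article_id: str = "N1", **overrides) -> ScreeningRecord:
    base = dict(
        article_id=article_id,
        journal=Journal.EHJ,
        study_type=StudyType.NON_EMPIRICAL,
        study_type_stated=True,
        materials_statement=AvailabilityStatement.NOT_APPLICABLE,
        data_statement=AvailabilityStatement.NOT_APPLICABLE,
        scripts_statement=AvailabilityStatement.NOT_APPLICABLE,
        coi_statement=CoiStatement.NO_COI,
        funding_statement=FundingStatement.PUBLIC,
        open_access=OpenAccess.YES_OTHER,
    )
    base.update(overrides)
    return ScreeningRecord(**base)


def recordset(*records: ScreeningRecord, provenance: str = "test") -> RecordSet:
    return RecordSet(records=tuple(records), provenance=provenance)
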