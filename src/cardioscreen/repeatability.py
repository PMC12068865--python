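"""Potential replicability / reproducibility classification.

Four resource categories determine repeatability: materials, methods, data,
and analysis scripts. "Methods" are present when the article has an
accessible pre-registration or a linked protocol. An article is

* *partially replicable* if any of {materials, scripts, methods} is
  available, and *fully replicable* if all three are;
* *partially reproducible* if any of {data, scripts, methods} is available,
  and *fully reproducible* if all three are;
* *partially repeatable* if it is partially replicable or partially
  reproducible.

The classification captures the *potential* to repeat a study from its shared
resources, not whether anyone repeated it. By default a resource counts as
available when the article *states* it is available; a stricter mode counts
only resources that were actually accessible (openable) during screening.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .schema_io import (
    AvailabilityStatement,
    RecordSet,
    ScreeningRecord,
    StudyAspect,
    StudyType,
    TriState,
)

__all__ = [
    "ResourceAvailability",
    "Level",
    "RepeatabilityStatus",
    "resource_availability",
    "classify",
    "classify_record",
    "classification_table",
]


@dataclass(frozen=True)
class ResourceAvailability:
    materials: bool
    methods: bool
    data: bool
    scripts: bool


class Level(str, Enum):
    NONE = "NONE"
    PARTIAL = "PARTIAL"
    FULL = "FULL"


@dataclass(frozen=True)
class RepeatabilityStatus:
    replicable: Level
    reproducible: Level
    partially_repeatable: bool


def resource_availability(
    record: ScreeningRecord,
    strict_access: bool = False,
    require_methods_aspect: bool = False,
) -> ResourceAvailability:
    """Map a record's coded responses onto the four resource categories.

    Parameters
    ----------
    strict_access
        If true, materials/data/scripts count only when the screener could
        actually access and open them, not merely when availability was
        stated.
    require_methods_aspect
        If true, the methods category additionally requires the
        pre-registration or protocol to cover the METHODS aspect; by default
        mere presence of an accessible pre-registration or linked protocol
        suffices.
    """
    if record.study_type is StudyType.NON_EMPIRICAL:
        raise ValueError("non-empirical articles are not classified")
    if strict_access:
        materials = record.materials_accessible is TriState.YES
        data = record.data_accessible is TriState.YES
        scripts = record.scripts_accessible is TriState.YES
    else:
        materials = record.materials_statement is AvailabilityStatement.YES_AVAILABLE
        data = record.data_statement is AvailabilityStatement.YES_AVAILABLE
        scripts = record.scripts_statement is AvailabilityStatement.YES_AVAILABLE
    if require_methods_aspect:
        methods = (
            record.prereg_accessible is TriState.YES
            and StudyAspect.METHODS in record.prereg_aspects
        ) or (record.protocol_linked and StudyAspect.METHODS in record.protocol_aspects)
    else:
        methods = record.prereg_accessible is TriState.YES or record.protocol_linked
    return ResourceAvailability(
        materials=materials, methods=methods, data=data, scripts=scripts
    )


def _level(triple: tuple[bool, bool, bool]) -> Level:
    if all(triple):
        return Level.FULL
    if any(triple):
        return Level.PARTIAL
    return Level.NONE


def classify(avail: ResourceAvailability) -> RepeatabilityStatus:
    """Classify from resource availability.

    Replicability (repeat with new data) rests on {materials, scripts,
    methods}; reproducibility (re-analyze the original data) on {data,
    scripts, methods}.
    """
    replicable = _level((avail.materials, avail.scripts, avail.methods))
    reproducible = _level((avail.data, avail.scripts, avail.methods))
    return RepeatabilityStatus(
        replicable=replicable,
        reproducible=reproducible,
        partially_repeatable=(replicable is not Level.NONE)
        or (reproducible is not Level.NONE),
    )


def classify_record(
    record: ScreeningRecord,
    strict_access: bool = False,
    require_methods_aspect: bool = False,
) -> RepeatabilityStatus:
    return classify(
        resource_availability(
            record,
            strict_access=strict_access,
            require_methods_aspect=require_methods_aspect,
        )
    )


def classification_table(rs: RecordSet, strict_access: bool = False) -> pd.DataFrame:
    """Per-article classification over the empirical records.

    Columns: article_id, replicable, reproducible, partially_repeatable.
    """
    rows = []
    for rec in rs.empirical:
        status = classify_record(rec, strict_access=strict_access)
        rows.append(
            {
                "article_id": rec.article_id,
                "replicable": status.replicable.value,
                "reproducible": status.reproducible.value,
                "partially_repeatable": status.partially_repeatable,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["article_id", "replicable", "reproducible", "partially_repeatable"],
    )
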