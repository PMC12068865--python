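"""Corpus-level summary report: tallies, percentages, histograms, batteries.

Percentage formatting follows the corpus-summary convention: values are
rounded half away from zero and both 0- and 1-decimal precisions are useful
depending on context, so :func:`percent` takes the precision explicitly.
Score histograms use left-closed bins of width 0.1 with 1.0 folded into the
top bin.

:func:`summarize` is a pure function of its RecordSet: non-empirical
articles appear only in corpus-wide tallies (journal/study-type mix, COI,
funding, open access), while scoring, availability chains, repeatability and
the test battery run on the empirical subset.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence

from . import repeatability, scoring, stats
from .schema_io import (
    AvailabilityStatement,
    PreregStatement,
    RecordSet,
    ScreeningRecord,
    StudyAspect,
    TriState,
)

__all__ = ["percent", "score_histogram", "summarize", "SummaryReport"]


def percent(numerator: int, denominator: int, decimals: int = 0) -> str:
    """Format ``100 * numerator / denominator`` as a percentage string.

    Rounds half away from zero (so 7/393 -> "2%" and 56/393 -> "14%").
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must lie in [0, denominator]")
    if decimals < 0:
        raise ValueError("decimals must be nonnegative")
    quantum = Decimal(1).scaleb(-decimals)
    value = (Decimal(numerator) * 100 / Decimal(denominator)).quantize(
        quantum, rounding=ROUND_HALF_UP
    )
    return f"{value}%"


#: Histogram bin labels, in order.
HISTOGRAM_BINS = tuple(f"{i / 10:.2f}–{i / 10 + 0.09:.2f}" for i in range(10))


def score_histogram(scores: Iterable[float]) -> dict[str, int]:
    """Counts of scores per width-0.1 bin; 1.0 falls in the top bin."""
    counts = {label: 0 for label in HISTOGRAM_BINS}
    for s in scores:
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"score {s!r} outside [0, 1]")
        idx = min(int(math.floor(s * 10)), 9)
        counts[HISTOGRAM_BINS[idx]] += 1
    return counts


@dataclass(frozen=True)
class ChainSummary:
    """Counts down one availability chain (each step conditions on the last)."""

    statement_yes: int
    states_unavailable: int
    no_statement: int
    not_applicable: int
    mode_counts: Mapping[str, int]
    accessible_yes: int
    documented_yes: int | None = None
    complete_yes: int | None = None


@dataclass(frozen=True)
class SummaryReport:
    provenance: str
    n_total: int
    n_empirical: int
    journal_counts: Mapping[str, int]
    study_type_counts: Mapping[str, int]
    study_type_stated: int
    coi_counts: Mapping[str, int]
    funding_counts: Mapping[str, int]
    open_access_counts: Mapping[str, int]
    availability: Mapping[str, ChainSummary]
    prereg_statement_yes: int
    prereg_accessible_yes: int
    prereg_aspect_counts: Mapping[str, int]
    prereg_completeness_counts: Mapping[int, int]
    protocol_linked: int
    protocol_aspect_counts: Mapping[str, int]
    repeatability_counts: Mapping[str, Mapping[str, int]]
    partially_repeatable: int
    histogram: Mapping[str, int]
    by_study_type: tuple[stats.GroupSummary, ...]
    by_journal: tuple[stats.GroupSummary, ...]
    battery: stats.BatteryResult | None
    battery_note: str = ""

    # -- rendering -----------------------------------------------------------

    def to_dict(self) -> dict:
        def gs(rows: Sequence[stats.GroupSummary]) -> list[dict]:
            return [
                {"group": r.group, "n": r.n, "mean": r.mean, "sd": r.sd} for r in rows
            ]

        d = {
            "provenance": self.provenance,
            "n_total": self.n_total,
            "n_empirical": self.n_empirical,
            "journal_counts": dict(self.journal_counts),
            "study_type_counts": dict(self.study_type_counts),
            "study_type_stated": self.study_type_stated,
            "study_type_stated_pct": [
                percent(self.study_type_stated, self.n_total, d) for d in (0, 1)
            ],
            "coi_counts": dict(self.coi_counts),
            "funding_counts": dict(self.funding_counts),
            "open_access_counts": dict(self.open_access_counts),
            "availability": {
                name: {
                    "statement_yes": c.statement_yes,
                    "states_unavailable": c.states_unavailable,
                    "no_statement": c.no_statement,
                    "not_applicable": c.not_applicable,
                    "mode_counts": dict(c.mode_counts),
                    "accessible_yes": c.accessible_yes,
                    **(
                        {"documented_yes": c.documented_yes, "complete_yes": c.complete_yes}
                        if c.documented_yes is not None
                        else {}
                    ),
                }
                for name, c in self.availability.items()
            },
            "prereg": {
                "statement_yes": self.prereg_statement_yes,
                "accessible_yes": self.prereg_accessible_yes,
                "aspect_counts": dict(self.prereg_aspect_counts),
                "completeness_counts": {
                    str(k): v for k, v in self.prereg_completeness_counts.items()
                },
            },
            "protocol": {
                "linked": self.protocol_linked,
                "aspect_counts": dict(self.protocol_aspect_counts),
            },
            "repeatability": {
                k: dict(v) for k, v in self.repeatability_counts.items()
            },
            "partially_repeatable": self.partially_repeatable,
            "score_histogram": dict(self.histogram),
            "scores_by_study_type": gs(self.by_study_type),
            "scores_by_journal": gs(self.by_journal),
        }
        if self.n_empirical:
            d["availability_pct"] = {
                name: [
                    percent(c.statement_yes, self.n_empirical, dd) for dd in (0, 1)
                ]
                for name, c in self.availability.items()
            }
            d["open_access_pct"] = [
                percent(
                    self.open_access_counts.get("YES_OA_BUTTON", 0)
                    + self.open_access_counts.get("YES_OTHER", 0),
                    self.n_total,
                    dd,
                )
                for dd in (0, 1)
            ]
        if self.battery is not None:
            d["battery"] = {
                "study_types": list(self.battery.study_types),
                "excluded_types": list(self.battery.excluded_types),
                "omnibus": self.battery.omnibus_frame().to_dict(orient="records"),
                "pairwise": self.battery.pairwise_frame().to_dict(orient="records"),
            }
        elif self.battery_note:
            d["battery_note"] = self.battery_note
        return d

    def to_json(self, indent: int | None = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, default=str)

    def to_markdown(self) -> str:
        lines: list[str] = [f"# Screening summary ({self.provenance or 'unnamed set'})", ""]
        lines.append(f"Articles screened: {self.n_total}; empirical: {self.n_empirical} "
                     f"({percent(self.n_empirical, self.n_total, 1)}).")
        lines.append("")
        lines.append(_md_table("Journal", self.journal_counts, self.n_total))
        lines.append(_md_table("Study type", self.study_type_counts, self.n_total))
        lines.append(_md_table("COI statement", self.coi_counts, self.n_total))
        lines.append(_md_table("Funding statement", self.funding_counts, self.n_total))
        lines.append(_md_table("Open access", self.open_access_counts, self.n_total))
        if self.n_empirical:
            lines.append("## Resource availability (empirical articles)")
            lines.append("")
            lines.append("| resource | stated available | accessible | % stated (0dp / 1dp) |")
            lines.append("| --- | --- | --- | --- |")
            for name, c in self.availability.items():
                lines.append(
                    f"| {name} | {c.statement_yes} | {c.accessible_yes} | "
                    f"{percent(c.statement_yes, self.n_empirical, 0)} / "
                    f"{percent(c.statement_yes, self.n_empirical, 1)} |"
                )
            lines.append("")
            lines.append("## Repeatability")
            lines.append("")
            lines.append("| status | NONE | PARTIAL | FULL |")
            lines.append("| --- | --- | --- | --- |")
            for kind in ("replicable", "reproducible"):
                row = self.repeatability_counts[kind]
                lines.append(
                    f"| {kind} | {row.get('NONE', 0)} | {row.get('PARTIAL', 0)} | "
                    f"{row.get('FULL', 0)} |"
                )
            lines.append("")
            lines.append(
                f"Partially repeatable: {self.partially_repeatable} "
                f"({percent(self.partially_repeatable, self.n_empirical, 1)})."
            )
            lines.append("")
            lines.append("## Accessibility score distribution")
            lines.append("")
            lines.append("| bin | count |")
            lines.append("| --- | --- |")
            for label, count in self.histogram.items():
                lines.append(f"| {label} | {count} |")
            lines.append("")
            for title, rows in (
                ("Scores by study type", self.by_study_type),
                ("Scores by journal", self.by_journal),
            ):
                lines.append(f"## {title}")
                lines.append("")
                lines.append("| group | n | mean | sd |")
                lines.append("| --- | --- | --- | --- |")
                for r in rows:
                    sd = "" if r.sd is None else f"{r.sd:.3f}"
                    lines.append(f"| {r.group} | {r.n} | {r.mean:.3f} | {sd} |")
                lines.append("")
        if self.battery is not None:
            lines.append("## Resource-sharing tests across study types")
            lines.append("")
            lines.append(_frame_md(self.battery.omnibus_frame()))
            lines.append("")
            lines.append(_frame_md(self.battery.pairwise_frame()))
            lines.append("")
        elif self.battery_note:
            lines.append(f"Test battery skipped: {self.battery_note}")
            lines.append("")
        return "\n".join(lines)


def _frame_md(frame) -> str:
    """Render a small DataFrame as a GitHub-flavored markdown table."""

    def fmt(v) -> str:
        if isinstance(v, float):
            return f"{v:.4g}"
        return "" if v is None else str(v)

    cols = list(frame.columns)
    lines = ["| " + " | ".join(cols) + " |", "| " + " | ".join("---" for _ in cols) + " |"]
    for _, row in frame.iterrows():
        lines.append("| " + " | ".join(fmt(row[c]) for c in cols) + " |")
    return "\n".join(lines)


def _md_table(title: str, counts: Mapping[str, int], denom: int) -> str:
    lines = [f"## {title}", "", "| value | count | % |", "| --- | --- | --- |"]
    for key, count in counts.items():
        lines.append(f"| {key} | {count} | {percent(count, denom, 1)} |")
    lines.append("")
    return "\n".join(lines)


def _chain_summary(
    records: Sequence[ScreeningRecord], prefix: str, with_data_chain: bool = False
) -> ChainSummary:
    def attr(rec, name):
        return getattr(rec, f"{prefix}_{name}")

    mode_counts: dict[str, int] = {}
    statement_yes = states_unavailable = no_statement = not_applicable = 0
    accessible_yes = 0
    documented_yes = complete_yes = 0
    for rec in records:
        st = attr(rec, "statement")
        if st is AvailabilityStatement.YES_AVAILABLE:
            statement_yes += 1
            mode = attr(rec, "mode").value
            mode_counts[mode] = mode_counts.get(mode, 0) + 1
        elif st is AvailabilityStatement.STATES_UNAVAILABLE:
            states_unavailable += 1
        elif st is AvailabilityStatement.NO_STATEMENT:
            no_statement += 1
        else:
            not_applicable += 1
        if attr(rec, "accessible") is TriState.YES:
            accessible_yes += 1
        if with_data_chain:
            if rec.data_documented is TriState.YES:
                documented_yes += 1
            if rec.data_complete is TriState.YES:
                complete_yes += 1
    return ChainSummary(
        statement_yes=statement_yes,
        states_unavailable=states_unavailable,
        no_statement=no_statement,
        not_applicable=not_applicable,
        mode_counts=mode_counts,
        accessible_yes=accessible_yes,
        documented_yes=documented_yes if with_data_chain else None,
        complete_yes=complete_yes if with_data_chain else None,
    )


def _enum_counts(values: Iterable) -> dict[str, int]:
    out: dict[str, int] = {}
    for v in values:
        key = v.value
        out[key] = out.get(key, 0) + 1
    return out


def summarize(
    records: RecordSet,
    min_group_size: int = 20,
    strict_access: bool = False,
    run_battery: bool = True,
) -> SummaryReport:
    """Build the full summary report for a RecordSet.

    The comparison battery is included when at least two study types clear
    ``min_group_size``; otherwise it is omitted with a note.
    """
    if len(records) == 0:
        raise ValueError("summarize requires a nonempty RecordSet")
    all_recs = records.records
    empirical = records.empirical

    aspect_counts = {a.value: 0 for a in StudyAspect}
    protocol_aspect_counts = {a.value: 0 for a in StudyAspect}
    completeness_counts = {0: 0, 1: 0, 2: 0, 3: 0}
    prereg_statement_yes = prereg_accessible_yes = protocol_linked = 0
    for rec in empirical:
        if rec.prereg_statement is PreregStatement.YES:
            prereg_statement_yes += 1
        if rec.prereg_accessible is TriState.YES:
            prereg_accessible_yes += 1
        for a in rec.prereg_aspects:
            aspect_counts[a.value] += 1
        for a in rec.protocol_aspects:
            protocol_aspect_counts[a.value] += 1
        if rec.protocol_linked:
            protocol_linked += 1
        completeness_counts[scoring.prereg_completeness(rec)] += 1

    repeat_counts = {
        "replicable": {lvl.value: 0 for lvl in repeatability.Level},
        "reproducible": {lvl.value: 0 for lvl in repeatability.Level},
    }
    partially_repeatable = 0
    for rec in empirical:
        status = repeatability.classify_record(rec, strict_access=strict_access)
        repeat_counts["replicable"][status.replicable.value] += 1
        repeat_counts["reproducible"][status.reproducible.value] += 1
        if status.partially_repeatable:
            partially_repeatable += 1

    scores = [(rec, scoring.score_record(rec).value) for rec in empirical]
    histogram = score_histogram([v for _, v in scores])
    by_study_type = (
        tuple(stats.group_summary([(r.study_type.value, v) for r, v in scores]))
        if scores
        else ()
    )
    by_journal = (
        tuple(stats.group_summary([(r.journal.value, v) for r, v in scores]))
        if scores
        else ()
    )

    battery = None
    battery_note = ""
    if run_battery and empirical:
        try:
            battery = stats.resource_battery(
                records, min_group_size=min_group_size, strict_access=strict_access
            )
        except ValueError as exc:
            battery_note = str(exc)
    elif not empirical:
        battery_note = "no empirical records"

    return SummaryReport(
        provenance=records.provenance,
        n_total=len(all_recs),
        n_empirical=len(empirical),
        journal_counts=_enum_counts(r.journal for r in all_recs),
        study_type_counts=_enum_counts(r.study_type for r in all_recs),
        study_type_stated=sum(1 for r in all_recs if r.study_type_stated),
        coi_counts=_enum_counts(r.coi_statement for r in all_recs),
        funding_counts=_enum_counts(r.funding_statement for r in all_recs),
        open_access_counts=_enum_counts(r.open_access for r in all_recs),
        availability={
            "materials": _chain_summary(empirical, "materials"),
            "data": _chain_summary(empirical, "data", with_data_chain=True),
            "scripts": _chain_summary(empirical, "scripts"),
        },
        prereg_statement_yes=prereg_statement_yes,
        prereg_accessible_yes=prereg_accessible_yes,
        prereg_aspect_counts=aspect_counts,
        prereg_completeness_counts=completeness_counts,
        protocol_linked=protocol_linked,
        protocol_aspect_counts=protocol_aspect_counts,
        repeatability_counts=repeat_counts,
        partially_repeatable=partially_repeatable,
        histogram=histogram,
        by_study_type=by_study_type,
        by_journal=by_journal,
        battery=battery,
        battery_note=battery_note,
    )
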