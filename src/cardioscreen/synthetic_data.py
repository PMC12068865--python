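"""Seedable synthetic screening-record generator.

Emulates a screened corpus of cardiovascular articles: a mix over three
journals, a study-type mix that includes non-empirical article types, and —
per study type — independent satisfaction probabilities for each coding item,
with gated chains (statement -> accessible -> documented -> complete) sampled
as Markov chains so that every generated record satisfies the schema
invariants.

The default configuration is calibrated to the printed marginal proportions
of the screened 2019 corpus (639 articles, 393 of them empirical): e.g. a
materials-availability statement in 56/393 empirical articles, data in
125/393, analysis scripts in 43/393, a pre-registration statement in 107/393
(106/107 of which were accessible), and open access for 605/639 of all
articles. Items are sampled independently given the study type, so *joint*
outcomes (such as the number of fully reproducible articles) are emergent
rather than calibrated; cells the corpus summary never printed (access-mode
mix, data completeness, the study-type split of the empirical pool beyond
case studies, the funding split of the non-absent mass) are uncalibrated
single choices documented in the package's methods note.

One integer seed drives a single ``numpy.random.default_rng`` stream for the
whole generation; identical seed and config give a bit-identical RecordSet.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .schema_io import (
    MATERIALS_EXEMPT_TYPES,
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

__all__ = [
    "GatedChain",
    "ItemProbabilities",
    "SimulationConfig",
    "default_config",
    "generate_records",
    "load_config",
    "save_config",
]

_PROB_TOL = 1e-9


def _check_prob(name: str, p: float) -> None:
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"{name}: probability {p!r} outside [0, 1]")


def _check_simplex(name: str, probs: Mapping) -> None:
    for k, p in probs.items():
        _check_prob(f"{name}[{k}]", p)
    if abs(sum(probs.values()) - 1.0) > _PROB_TOL:
        raise ValueError(f"{name}: probabilities must sum to 1")


@dataclass(frozen=True)
class GatedChain:
    """Probabilities of one statement -> mode -> accessible chain.

    ``statement`` is P(availability is stated); ``states_unavailable`` is
    P(the statement explicitly denies availability | availability not
    stated); ``accessible`` is P(the resource could be opened | stated);
    ``mode_probs`` distributes the claimed access mode given a positive
    statement.
    """

    statement: float
    accessible: float
    states_unavailable: float = 0.05
    mode_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            AccessMode.UPON_REQUEST.value: 0.55,
            AccessMode.SUPPLEMENT.value: 0.20,
            AccessMode.REPOSITORY.value: 0.15,
            AccessMode.PERSONAL_OR_INSTITUTIONAL_PAGE.value: 0.10,
        }
    )

    def validate(self, name: str) -> None:
        _check_prob(f"{name}.statement", self.statement)
        _check_prob(f"{name}.accessible", self.accessible)
        _check_prob(f"{name}.states_unavailable", self.states_unavailable)
        _check_simplex(f"{name}.mode_probs", self.mode_probs)
        if AccessMode.NONE.value in self.mode_probs:
            raise ValueError(f"{name}.mode_probs: NONE is not a claimable mode")


@dataclass(frozen=True)
class ItemProbabilities:
    """Per-study-type satisfaction probabilities for every coding item.

    ``materials`` is None for study types that cannot share materials.
    Aspect probabilities are independent per aspect, conditional on the
    pre-registration being accessible (resp. the protocol being linked).
    """

    study_type_stated: float
    materials: GatedChain | None
    data: GatedChain
    scripts: GatedChain
    data_documented: float  # | data accessible
    data_complete: float  # | data documented
    prereg_statement: float
    prereg_accessible: float  # | statement
    prereg_aspects: Mapping[str, float]
    protocol_linked: float
    protocol_aspects: Mapping[str, float]

    def validate(self, name: str) -> None:
        _check_prob(f"{name}.study_type_stated", self.study_type_stated)
        if self.materials is not None:
            self.materials.validate(f"{name}.materials")
        self.data.validate(f"{name}.data")
        self.scripts.validate(f"{name}.scripts")
        for attr in (
            "data_documented",
            "data_complete",
            "prereg_statement",
            "prereg_accessible",
            "protocol_linked",
        ):
            _check_prob(f"{name}.{attr}", getattr(self, attr))
        for aspects_name in ("prereg_aspects", "protocol_aspects"):
            probs = getattr(self, aspects_name)
            if set(probs) != {a.value for a in StudyAspect}:
                raise ValueError(f"{name}.{aspects_name}: must cover all three aspects")
            for k, p in probs.items():
                _check_prob(f"{name}.{aspects_name}[{k}]", p)


@dataclass(frozen=True)
class SimulationConfig:
    n_articles: int
    journal_probs: Mapping[str, float]
    study_type_probs: Mapping[str, float]
    items: Mapping[str, ItemProbabilities]  # keyed by empirical study type
    coi_probs: Mapping[str, float]
    funding_probs: Mapping[str, float]
    open_access_probs: Mapping[str, float]
    seed: int = 0

    def validate(self) -> None:
        if self.n_articles < 0:
            raise ValueError("n_articles must be nonnegative")
        if set(self.journal_probs) != {j.value for j in Journal}:
            raise ValueError("journal_probs must cover exactly the three journals")
        _check_simplex("journal_probs", self.journal_probs)
        if set(self.study_type_probs) != {st.value for st in StudyType}:
            raise ValueError("study_type_probs must cover every study type")
        _check_simplex("study_type_probs", self.study_type_probs)
        _check_simplex("coi_probs", self.coi_probs)
        _check_simplex("funding_probs", self.funding_probs)
        _check_simplex("open_access_probs", self.open_access_probs)
        empirical_types = {st.value for st in StudyType} - {StudyType.NON_EMPIRICAL.value}
        if set(self.items) != empirical_types:
            raise ValueError("items must cover exactly the empirical study types")
        for st_name, item in self.items.items():
            item.validate(f"items[{st_name}]")
            exempt = StudyType(st_name) in MATERIALS_EXEMPT_TYPES
            if exempt and item.materials is not None:
                raise ValueError(
                    f"items[{st_name}].materials must be None (no shareable materials)"
                )
            if not exempt and item.materials is None:
                raise ValueError(f"items[{st_name}].materials must be a GatedChain")


# --- default, corpus-calibrated configuration -------------------------------

# Printed marginals of the screened corpus (639 articles, 393 empirical).
_N_ALL, _N_EMP = 639, 393

_DEF_MATERIALS = GatedChain(statement=56 / 393, accessible=1 / 56)
_DEF_DATA = GatedChain(statement=125 / 393, accessible=13 / 125)
_DEF_SCRIPTS = GatedChain(statement=43 / 393, accessible=1 / 43)

_DEF_PREREG_ASPECTS = {
    # per-aspect prevalence among accessible pre-registrations
    StudyAspect.HYPOTHESES.value: 44 / 106,
    StudyAspect.METHODS.value: 106 / 106,
    StudyAspect.ANALYSIS_PLAN.value: 27 / 106,
}
_DEF_PROTOCOL_ASPECTS = {
    StudyAspect.HYPOTHESES.value: 7 / 10,
    StudyAspect.METHODS.value: 9 / 10,
    StudyAspect.ANALYSIS_PLAN.value: 5 / 10,
}

# Empirical study-type mix: non-empirical 246/639 and case studies 21/393
# are printed; the remaining split is an uncalibrated choice (see methods
# note), with four deliberately small types so that sample-size exclusion
# in the test battery is exercised.
_DEF_STUDY_TYPE_COUNTS = {
    StudyType.NON_EMPIRICAL.value: 246,
    StudyType.CLINICAL_OBSERVATIONAL.value: 170,
    StudyType.CLINICAL_TRIAL.value: 90,
    StudyType.LAB_ANIMAL.value: 60,
    StudyType.CASE_STUDY_OR_SERIES.value: 21,
    StudyType.CLINICAL_INTERVENTION.value: 13,
    StudyType.LAB_CELL_MOLECULAR.value: 13,
    StudyType.META_ANALYSIS_SYSTEMATIC_REVIEW.value: 13,
    StudyType.NONCLINICAL_SECONDARY_DATA.value: 13,
}


def _default_items(study_type: StudyType) -> ItemProbabilities:
    exempt = study_type in MATERIALS_EXEMPT_TYPES
    return ItemProbabilities(
        study_type_stated=0.56,
        materials=None if exempt else _DEF_MATERIALS,
        data=_DEF_DATA,
        scripts=_DEF_SCRIPTS,
        data_documented=9 / 13,
        data_complete=0.5,  # unprinted; uncalibrated
        prereg_statement=107 / 393,
        prereg_accessible=106 / 107,
        prereg_aspects=dict(_DEF_PREREG_ASPECTS),
        protocol_linked=10 / 393,
        protocol_aspects=dict(_DEF_PROTOCOL_ASPECTS),
    )


def default_config(n_articles: int = 639, seed: int = 0) -> SimulationConfig:
    """Configuration calibrated to the screened corpus's printed marginals."""
    oa_yes = 605 / 639
    funding_absent = 276 / 639
    cfg = SimulationConfig(
        n_articles=n_articles,
        journal_probs={
            Journal.CIRCULATION.value: 226 / 639,
            Journal.EHJ.value: 193 / 639,
            Journal.JACC.value: 220 / 639,
        },
        study_type_probs={
            st: n / _N_ALL for st, n in _DEF_STUDY_TYPE_COUNTS.items()
        },
        items={
            st.value: _default_items(st)
            for st in StudyType
            if st is not StudyType.NON_EMPIRICAL
        },
        coi_probs={
            CoiStatement.HAS_COI.value: 0.57,
            CoiStatement.NO_COI.value: 0.36,
            CoiStatement.ABSENT.value: 0.07,
        },
        funding_probs={
            FundingStatement.ABSENT.value: funding_absent,
            # unprinted split of the non-absent mass; uniform
            FundingStatement.PRIVATE.value: (1 - funding_absent) / 4,
            FundingStatement.PUBLIC.value: (1 - funding_absent) / 4,
            FundingStatement.BOTH.value: (1 - funding_absent) / 4,
            FundingStatement.NO_FUNDING.value: (1 - funding_absent) / 4,
        },
        open_access_probs={
            # OA-button vs other split unprinted; split evenly
            OpenAccess.YES_OA_BUTTON.value: oa_yes / 2,
            OpenAccess.YES_OTHER.value: oa_yes / 2,
            OpenAccess.NO.value: 1 - oa_yes,
        },
        seed=seed,
    )
    cfg.validate()
    return cfg


# --- sampling ---------------------------------------------------------------


def _choice(rng: np.random.Generator, probs: Mapping[str, float]) -> str:
    keys = list(probs)
    return keys[rng.choice(len(keys), p=np.asarray([probs[k] for k in keys]))]


def _bern(rng: np.random.Generator, p: float) -> bool:
    return bool(rng.random() < p)


def _sample_chain(rng: np.random.Generator, chain: GatedChain | None):
    """Sample (statement, mode, accessible) respecting the gating invariants."""
    if chain is None:
        return (
            AvailabilityStatement.NOT_APPLICABLE,
            AccessMode.NONE,
            TriState.NOT_APPLICABLE,
        )
    if _bern(rng, chain.statement):
        mode = AccessMode(_choice(rng, chain.mode_probs))
        accessible = TriState.YES if _bern(rng, chain.accessible) else TriState.NO
        return AvailabilityStatement.YES_AVAILABLE, mode, accessible
    statement = (
        AvailabilityStatement.STATES_UNAVAILABLE
        if _bern(rng, chain.states_unavailable)
        else AvailabilityStatement.NO_STATEMENT
    )
    return statement, AccessMode.NONE, TriState.NOT_APPLICABLE


def _sample_aspects(
    rng: np.random.Generator, probs: Mapping[str, float]
) -> frozenset[StudyAspect]:
    return frozenset(
        StudyAspect(name)
        for name in (a.value for a in StudyAspect)
        if _bern(rng, probs[name])
    )


def generate_records(config: SimulationConfig) -> RecordSet:
    """Draw ``config.n_articles`` independent records from the configured mix."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    records: list[ScreeningRecord] = []
    for i in range(config.n_articles):
        journal = Journal(_choice(rng, config.journal_probs))
        study_type = StudyType(_choice(rng, config.study_type_probs))
        coi = CoiStatement(_choice(rng, config.coi_probs))
        funding = FundingStatement(_choice(rng, config.funding_probs))
        open_access = OpenAccess(_choice(rng, config.open_access_probs))
        article_id = f"SYN-{i:06d}"

        if study_type is StudyType.NON_EMPIRICAL:
            records.append(
                ScreeningRecord(
                    article_id=article_id,
                    journal=journal,
                    study_type=study_type,
                    study_type_stated=_bern(rng, 0.56),
                    materials_statement=AvailabilityStatement.NOT_APPLICABLE,
                    data_statement=AvailabilityStatement.NOT_APPLICABLE,
                    scripts_statement=AvailabilityStatement.NOT_APPLICABLE,
                    coi_statement=coi,
                    funding_statement=funding,
                    open_access=open_access,
                )
            )
            continue

        item = config.items[study_type.value]
        mat_stmt, mat_mode, mat_acc = _sample_chain(rng, item.materials)
        dat_stmt, dat_mode, dat_acc = _sample_chain(rng, item.data)
        scr_stmt, scr_mode, scr_acc = _sample_chain(rng, item.scripts)

        documented = (
            (TriState.YES if _bern(rng, item.data_documented) else TriState.NO)
            if dat_acc is TriState.YES
            else TriState.NOT_APPLICABLE
        )
        complete = (
            (TriState.YES if _bern(rng, item.data_complete) else TriState.NO)
            if documented is TriState.YES
            else TriState.NOT_APPLICABLE
        )

        if _bern(rng, item.prereg_statement):
            prereg_statement = PreregStatement.YES
            prereg_accessible = (
                TriState.YES if _bern(rng, item.prereg_accessible) else TriState.NO
            )
        else:
            prereg_statement = PreregStatement.NO
            prereg_accessible = TriState.NOT_APPLICABLE
        prereg_aspects = (
            _sample_aspects(rng, item.prereg_aspects)
            if prereg_accessible is TriState.YES
            else frozenset()
        )
        protocol_linked = _bern(rng, item.protocol_linked)
        protocol_aspects = (
            _sample_aspects(rng, item.protocol_aspects)
            if protocol_linked
            else frozenset()
        )

        records.append(
            ScreeningRecord(
                article_id=article_id,
                journal=journal,
                study_type=study_type,
                study_type_stated=_bern(rng, item.study_type_stated),
                materials_statement=mat_stmt,
                materials_mode=mat_mode,
                materials_accessible=mat_acc,
                data_statement=dat_stmt,
                data_mode=dat_mode,
                data_accessible=dat_acc,
                data_documented=documented,
                data_complete=complete,
                scripts_statement=scr_stmt,
                scripts_mode=scr_mode,
                scripts_accessible=scr_acc,
                prereg_statement=prereg_statement,
                prereg_accessible=prereg_accessible,
                prereg_aspects=prereg_aspects,
                protocol_linked=protocol_linked,
                protocol_aspects=protocol_aspects,
                coi_statement=coi,
                funding_statement=funding,
                open_access=open_access,
            )
        )
    return RecordSet(
        records=tuple(records),
        provenance=f"synthetic seed={config.seed} n={config.n_articles}",
    )


# --- config (de)serialization ------------------------------------------------


def save_config(config: SimulationConfig, path: str | Path) -> None:
    """Write a config as YAML (or JSON if the suffix is .json)."""
    path = Path(path)
    d = asdict(config)
    with path.open("w", encoding="utf-8") as fh:
        if path.suffix.lower() == ".json":
            json.dump(d, fh, indent=2)
        else:
            yaml.safe_dump(d, fh, sort_keys=False)


def _chain_from_dict(d: dict | None) -> GatedChain | None:
    if d is None:
        return None
    return GatedChain(**d)


def load_config(path: str | Path) -> SimulationConfig:
    """Read a YAML or JSON config file."""
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        d = yaml.safe_load(fh)
    items = {
        st: ItemProbabilities(
            **{
                **item,
                "materials": _chain_from_dict(item["materials"]),
                "data": _chain_from_dict(item["data"]),
                "scripts": _chain_from_dict(item["scripts"]),
            }
        )
        for st, item in d["items"].items()
    }
    cfg = SimulationConfig(
        n_articles=int(d["n_articles"]),
        journal_probs=d["journal_probs"],
        study_type_probs=d["study_type_probs"],
        items=items,
        coi_probs=d["coi_probs"],
        funding_probs=d["funding_probs"],
        open_access_probs=d["open_access_probs"],
        seed=int(d.get("seed", 0)),
    )
    cfg.validate()
    return cfg
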