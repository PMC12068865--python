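"""Statistical comparison battery for screening-record analyses.

Implements the tests used to compare transparency across study types and
journals:

* per-group summaries (n, mean, sample SD) of accessibility scores;
* an unbalanced two-way ANOVA of score on study type and journal (Type II
  sums of squares, interaction tested from the full model);
* k x 2 chi-squared tests of homogeneity of a yes/no proportion across
  groups (no continuity correction);
* the two-sided Fisher exact test for 2 x 2 tables under the
  point-probability rule, computed with exact integer hypergeometric
  weights so ties are resolved exactly;
* Bonferroni adjustment with a ceiling at 1;
* :func:`resource_battery`, which strings these together: one omnibus k x 2
  test per resource category across study types, plus every pairwise 2 x 2
  study-type comparison per resource, falling back to Fisher's exact test
  whenever an observed cell is zero.

Significance is conventionally assessed at alpha = 0.05 on the adjusted
p-values.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from enum import Enum
from math import comb, inf
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ValueWarning

from .repeatability import resource_availability
from .schema_io import MATERIALS_EXEMPT_TYPES, RecordSet, StudyType

__all__ = [
    "Method",
    "TestResult",
    "GroupSummary",
    "ContingencyTable",
    "ALPHA",
    "RESOURCES",
    "group_summary",
    "two_way_anova",
    "chi2_homogeneity",
    "fisher_exact_2x2",
    "bonferroni_adjust",
    "resource_battery",
    "BatteryResult",
    "PairwiseComparison",
]

#: Conventional significance threshold for adjusted p-values.
ALPHA = 0.05

#: The four repeatability resource categories compared by the battery.
RESOURCES = ("materials", "methods", "data", "analysis")

_ZERO_SS = 1e-12  # sums of squares below this are treated as exactly zero


class Method(str, Enum):
    CHI2 = "CHI2"
    FISHER = "FISHER"
    ANOVA_F = "ANOVA_F"


@dataclass(frozen=True)
class TestResult:
    method: Method
    statistic: float
    df: float | tuple[float, float] | None
    p_raw: float
    p_adjusted: float | None = None

    def adjusted(self, p_adjusted: float) -> "TestResult":
        return TestResult(self.method, self.statistic, self.df, self.p_raw, p_adjusted)


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n: int
    mean: float
    sd: float | None  # sample SD; None when n == 1


@dataclass(frozen=True)
class ContingencyTable:
    """A k x 2 table of (yes, no) counts per group."""

    row_labels: tuple[str, ...]
    counts: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if len(self.row_labels) != len(self.counts):
            raise ValueError("row_labels and counts must have equal length")
        if len(self.counts) < 2:
            raise ValueError("a contingency table needs at least 2 rows")
        for row in self.counts:
            if len(row) != 2:
                raise ValueError("each row must hold (yes, no) counts")
            if any(c < 0 or int(c) != c for c in row):
                raise ValueError("counts must be nonnegative integers")
        if all(sum(row) == 0 for row in self.counts):
            raise ValueError("at least one row total must be positive")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=np.int64)

    def has_zero_cell(self) -> bool:
        return any(c == 0 for row in self.counts for c in row)


def group_summary(scores: Iterable[tuple[str, float]]) -> list[GroupSummary]:
    """Per-group n, mean and sample standard deviation (ddof=1).

    The SD is left unset for singleton groups. Groups are returned in sorted
    label order.
    """
    pairs = list(scores)
    if not pairs:
        raise ValueError("group_summary requires at least one observation")
    for g, v in pairs:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"score {v!r} in group {g!r} outside [0, 1]")
    frame = pd.DataFrame(pairs, columns=["group", "value"])
    out: list[GroupSummary] = []
    for label, chunk in frame.groupby("group", sort=True):
        n = len(chunk)
        out.append(
            GroupSummary(
                group=str(label),
                n=n,
                mean=float(chunk["value"].mean()),
                sd=float(chunk["value"].std(ddof=1)) if n > 1 else None,
            )
        )
    return out


def two_way_anova(
    obs: Iterable[tuple[float, str, str]],
    factor_names: tuple[str, str] = ("study_type", "journal"),
) -> dict[str, TestResult]:
    """Unbalanced two-way ANOVA with interaction, Type II sums of squares.

    Parameters
    ----------
    obs
        (value, level of factor A, level of factor B) triples.

    Returns
    -------
    dict mapping ``factor_names[0]``, ``factor_names[1]`` and
    ``"interaction"`` to :class:`TestResult` with an F statistic, a
    (df_effect, df_residual) pair and the F-distribution p-value.

    Effects whose sum of squares vanishes (e.g. constant data) are reported
    as F = 0, p = 1; a positive effect over a zero residual gives F = inf,
    p = 0.
    """
    frame = pd.DataFrame(list(obs), columns=["value", "_fa", "_fb"])
    if frame.empty:
        raise ValueError("two_way_anova requires observations")
    for col, name in (("_fa", factor_names[0]), ("_fb", factor_names[1])):
        if frame[col].nunique() < 2:
            raise ValueError(f"factor {name!r} has fewer than 2 levels")
    model = smf.ols("value ~ C(_fa) + C(_fb) + C(_fa):C(_fb)", data=frame).fit()
    # Empty cells leave the interaction design rank-deficient; the fit uses a
    # pseudoinverse and the anova table's F/p are recomputed below, so the
    # rank warning carries no extra information for callers.
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", ValueWarning)
        table = sm.stats.anova_lm(model, typ=2)
    resid_ss = float(table.loc["Residual", "sum_sq"])
    resid_df = float(table.loc["Residual", "df"])
    keys = {
        "C(_fa)": factor_names[0],
        "C(_fb)": factor_names[1],
        "C(_fa):C(_fb)": "interaction",
    }
    results: dict[str, TestResult] = {}
    for row_name, out_name in keys.items():
        eff_ss = float(table.loc[row_name, "sum_sq"])
        eff_df = float(table.loc[row_name, "df"])
        if eff_ss < _ZERO_SS or eff_df <= 0:
            f_stat, p = 0.0, 1.0
        elif resid_ss < _ZERO_SS or resid_df <= 0:
            f_stat, p = inf, 0.0
        else:
            f_stat = (eff_ss / eff_df) / (resid_ss / resid_df)
            p = float(scipy.stats.f.sf(f_stat, eff_df, resid_df))
        results[out_name] = TestResult(
            method=Method.ANOVA_F,
            statistic=f_stat,
            df=(eff_df, resid_df),
            p_raw=p,
        )
    return results


def chi2_homogeneity(t: ContingencyTable) -> TestResult:
    """k x 2 chi-squared test of equal yes-proportions across groups.

    Expected counts come from the row/column margins; no continuity
    correction is applied; df = k - 1. Requires every row total and both
    column totals to be positive (otherwise an expected count is zero) —
    for 2 x 2 tables with a zero cell use :func:`fisher_exact_2x2` instead.
    """
    counts = t.array
    if (counts.sum(axis=1) == 0).any():
        raise ValueError("zero row total: expected counts undefined")
    if (counts.sum(axis=0) == 0).any():
        raise ValueError("zero column total: expected counts undefined")
    stat, p, df, _ = scipy.stats.chi2_contingency(counts, correction=False)
    return TestResult(method=Method.CHI2, statistic=float(stat), df=float(df), p_raw=float(p))


def fisher_exact_2x2(t: ContingencyTable) -> TestResult:
    """Two-sided Fisher exact test for a 2 x 2 table.

    With margins fixed, the two-sided p-value is the sum of hypergeometric
    point probabilities no larger than that of the observed table (the
    point-probability rule). Point weights are compared as exact integers,
    so probability ties are included without floating-point ambiguity. The
    ``statistic`` field carries the observed table's point probability.
    """
    counts = t.array
    if counts.shape != (2, 2):
        raise ValueError("fisher_exact_2x2 requires a 2 x 2 table")
    a, b = int(counts[0, 0]), int(counts[0, 1])
    c, d = int(counts[1, 0]), int(counts[1, 1])
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    total = comb(n, c1)
    w_obs = comb(r1, a) * comb(r2, c1 - a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_sum = 0
    for x in range(lo, hi + 1):
        w = comb(r1, x) * comb(r2, c1 - x)
        if w <= w_obs:
            p_sum += w
    return TestResult(
        method=Method.FISHER,
        statistic=w_obs / total,
        df=None,
        p_raw=p_sum / total,
    )


def bonferroni_adjust(p_values: Sequence[float], m: int) -> list[float]:
    """min(1, m * p) for each raw p-value; order-preserving."""
    ps = list(p_values)
    if m < len(ps):
        raise ValueError("m must be at least the number of p-values")
    for p in ps:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value {p!r} outside [0, 1]")
    return [min(1.0, m * p) for p in ps]


@dataclass(frozen=True)
class PairwiseComparison:
    resource: str
    group_a: str
    group_b: str
    table: ContingencyTable
    result: TestResult


@dataclass(frozen=True)
class BatteryResult:
    """Omnibus per-resource tests plus all pairwise study-type comparisons."""

    study_types: tuple[str, ...]
    omnibus: Mapping[str, tuple[ContingencyTable, TestResult]]
    pairwise: tuple[PairwiseComparison, ...]
    excluded_types: tuple[str, ...] = ()

    def omnibus_frame(self) -> pd.DataFrame:
        rows = []
        for resource, (table, res) in self.omnibus.items():
            arr = table.array
            rows.append(
                {
                    "resource": resource,
                    "yes": int(arr[:, 0].sum()),
                    "no": int(arr[:, 1].sum()),
                    "method": res.method.value,
                    "statistic": res.statistic,
                    "df": res.df,
                    "p_raw": res.p_raw,
                    "p_adjusted": res.p_adjusted,
                }
            )
        return pd.DataFrame(rows)

    def pairwise_frame(self) -> pd.DataFrame:
        rows = [
            {
                "resource": pc.resource,
                "group_a": pc.group_a,
                "group_b": pc.group_b,
                "method": pc.result.method.value,
                "statistic": pc.result.statistic,
                "p_raw": pc.result.p_raw,
                "p_adjusted": pc.result.p_adjusted,
            }
            for pc in self.pairwise
        ]
        return pd.DataFrame(rows)

    def pairwise_matrix(self) -> pd.DataFrame:
        """Adjusted p-values pivoted as comparison x resource."""
        frame = self.pairwise_frame()
        frame["comparison"] = frame["group_a"] + " vs " + frame["group_b"]
        return frame.pivot(index="comparison", columns="resource", values="p_adjusted")


def _resource_flags(record, strict_access: bool) -> dict[str, bool]:
    avail = resource_availability(record, strict_access=strict_access)
    return {
        "materials": avail.materials,
        "methods": avail.methods,
        "data": avail.data,
        "analysis": avail.scripts,
    }


def resource_battery(
    rs: RecordSet,
    min_group_size: int = 20,
    strict_access: bool = False,
    m_omnibus: int | None = None,
    m_pairwise: int | None = None,
    expected_count_fallback: bool = False,
) -> BatteryResult:
    """Run the full resource-by-study-type comparison battery.

    Study types with fewer than ``min_group_size`` empirical articles are
    excluded. For each resource category an omnibus k x 2 chi-squared test
    compares the sharing proportion across the retained study types
    (materials-exempt types are omitted from the materials tables); every
    pair of study types is then compared per resource with a 2 x 2
    chi-squared test, switching to Fisher's exact test whenever the observed
    table has a zero cell (or, with ``expected_count_fallback``, whenever an
    expected count falls below 5).

    Bonferroni families: the omnibus p-values are adjusted for the number of
    resources tested (``m_omnibus``, default 4) and the pairwise p-values
    for the total number of pairwise tests across all resources
    (``m_pairwise``, default C(k,2) x 4).
    """
    empirical = rs.empirical
    counts_by_type: dict[StudyType, int] = {}
    for rec in empirical:
        counts_by_type[rec.study_type] = counts_by_type.get(rec.study_type, 0) + 1
    eligible = sorted(
        (st for st, n in counts_by_type.items() if n >= min_group_size),
        key=lambda st: st.value,
    )
    excluded = sorted(
        (st.value for st, n in counts_by_type.items() if n < min_group_size)
    )
    if len(eligible) < 2:
        raise ValueError(
            f"resource_battery needs >=2 study types with n >= {min_group_size}; "
            f"got {len(eligible)}"
        )

    # yes/no counts per (resource, study type)
    tallies: dict[str, dict[StudyType, list[int]]] = {
        res: {st: [0, 0] for st in eligible} for res in RESOURCES
    }
    for rec in empirical:
        if rec.study_type not in tallies["data"]:
            continue
        flags = _resource_flags(rec, strict_access)
        for res in RESOURCES:
            if res == "materials" and rec.study_type in MATERIALS_EXEMPT_TYPES:
                continue
            tallies[res][rec.study_type][0 if flags[res] else 1] += 1

    def table_for(res: str, types: Sequence[StudyType]) -> ContingencyTable:
        types = [
            st
            for st in types
            if not (res == "materials" and st in MATERIALS_EXEMPT_TYPES)
        ]
        return ContingencyTable(
            row_labels=tuple(st.value for st in types),
            counts=tuple(tuple(tallies[res][st]) for st in types),
        )

    omnibus_raw: dict[str, tuple[ContingencyTable, TestResult]] = {}
    for res in RESOURCES:
        table = table_for(res, eligible)
        omnibus_raw[res] = (table, chi2_homogeneity(table))
    m_omni = m_omnibus if m_omnibus is not None else len(RESOURCES)
    adj = bonferroni_adjust([r.p_raw for _, r in omnibus_raw.values()], m_omni)
    omnibus = {
        res: (table, result.adjusted(p_adj))
        for (res, (table, result)), p_adj in zip(omnibus_raw.items(), adj)
    }

    pairs = list(itertools.combinations(eligible, 2))
    pairwise_raw: list[PairwiseComparison] = []
    for res in RESOURCES:
        for st_a, st_b in pairs:
            if res == "materials" and (
                st_a in MATERIALS_EXEMPT_TYPES or st_b in MATERIALS_EXEMPT_TYPES
            ):
                continue
            table = table_for(res, [st_a, st_b])
            use_fisher = table.has_zero_cell()
            if expected_count_fallback and not use_fisher:
                arr = table.array.astype(float)
                expected = np.outer(arr.sum(axis=1), arr.sum(axis=0)) / arr.sum()
                use_fisher = bool((expected < 5).any())
            result = fisher_exact_2x2(table) if use_fisher else chi2_homogeneity(table)
            pairwise_raw.append(
                PairwiseComparison(
                    resource=res,
                    group_a=st_a.value,
                    group_b=st_b.value,
                    table=table,
                    result=result,
                )
            )
    m_pair = m_pairwise if m_pairwise is not None else len(pairs) * len(RESOURCES)
    adj = bonferroni_adjust([pc.result.p_raw for pc in pairwise_raw], m_pair)
    pairwise = tuple(
        PairwiseComparison(
            resource=pc.resource,
            group_a=pc.group_a,
            group_b=pc.group_b,
            table=pc.table,
            result=pc.result.adjusted(p_adj),
        )
        for pc, p_adj in zip(pairwise_raw, adj)
    )
    return BatteryResult(
        study_types=tuple(st.value for st in eligible),
        omnibus=omnibus,
        pairwise=pairwise,
        excluded_types=tuple(excluded),
    )
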