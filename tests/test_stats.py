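"""Statistical battery: summaries, ANOVA, chi-squared, Fisher, Bonferroni."""

import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st

from cardioscreen.schema_io import (
    AccessMode,
    AvailabilityStatement,
    PreregStatement,
    RecordSet,
    StudyType,
    TriState,
)
from cardioscreen.stats import (
    ContingencyTable,
    Method,
    bonferroni_adjust,
    chi2_homogeneity,
    fisher_exact_2x2,
    group_summary,
    resource_battery,
    two_way_anova,
)

from _factories import negative_record


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Brute-force two-sided Fisher p by exact hypergeometric enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def pmf(x: int) -> Fraction:
        return Fraction(comb(r1, x) * comb(r2, c1 - x), comb(n, c1))

    p_obs = pmf(a)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = pmf(x)
        if px <= p_obs:
            total += px
    return float(total)


class TestGroupSummary:
    def test_singleton_group_has_no_sd(self):
        (g,) = group_summary([("trial", 0.4)])
        assert (g.n, g.mean, g.sd) == (1, 0.4, None)

    def test_two_value_group_matches_hand_computed_sample_sd(self):
        # mean 0.3; sample SD = sqrt(((0.1)^2 + (0.1)^2) / 1) = 0.141421...
        (g,) = group_summary([("obs", 0.2), ("obs", 0.4)])
        assert g.mean == pytest.approx(0.3)
        assert g.sd == pytest.approx(0.14142135623, abs=1e-9)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            group_summary([])

    def test_out_of_range_score_rejected(self):
        with pytest.raises(ValueError):
            group_summary([("obs", 1.2)])


class TestTwoWayAnova:
    def test_constant_data_gives_zero_f_unit_p(self):
        obs = [
            (0.5, a, b)
            for a in ("t1", "t2")
            for b in ("j1", "j2")
            for _ in range(3)
        ]
        res = two_way_anova(obs, factor_names=("type", "journal"))
        for key in ("type", "journal", "interaction"):
            assert res[key].statistic == 0.0
            assert res[key].p_raw == 1.0

    def test_balanced_2x2_matches_hand_decomposition(self):
        # Cell means 0.2/0.4/0.6/0.8 with +-0.05 replicates:
        # SSA = 0.32, SSB = 0.08, SSAB = 0, SSE = 0.02 on 4 df
        # => F_A = 64, F_B = 16, interaction SS = 0 => F = 0, p = 1.
        obs = []
        for a, b, m in (("a1", "b1", 0.2), ("a1", "b2", 0.4),
                        ("a2", "b1", 0.6), ("a2", "b2", 0.8)):
            obs += [(m - 0.05, a, b), (m + 0.05, a, b)]
        res = two_way_anova(obs, factor_names=("A", "B"))
        assert res["A"].statistic == pytest.approx(64.0, abs=1e-8)
        assert res["A"].df == (1.0, 4.0)
        assert res["A"].p_raw == pytest.approx(scipy.stats.f.sf(64.0, 1, 4))
        assert res["B"].statistic == pytest.approx(16.0, abs=1e-8)
        assert res["interaction"].statistic == 0.0
        assert res["interaction"].p_raw == 1.0

    def test_single_level_factor_errors(self):
        obs = [(0.1, "t1", "j1"), (0.2, "t1", "j2")]
        with pytest.raises(ValueError, match="fewer than 2 levels"):
            two_way_anova(obs)

    def test_noiseless_effect_gives_infinite_f(self):
        obs = []
        for a, b, m in (("a1", "b1", 0.2), ("a1", "b2", 0.4),
                        ("a2", "b1", 0.6), ("a2", "b2", 0.8)):
            obs += [(m, a, b), (m, a, b)]
        res = two_way_anova(obs, factor_names=("A", "B"))
        assert res["A"].statistic == float("inf")
        assert res["A"].p_raw == 0.0


class TestChi2Homogeneity:
    def test_homogeneous_table_statistic_zero(self):
        t = ContingencyTable(("g1", "g2"), ((10, 10), (10, 10)))
        res = chi2_homogeneity(t)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_raw == pytest.approx(1.0)

    def test_hand_derived_statistic(self):
        # margins: rows 100/100, columns 60/140 => expected (30,70) per row;
        # sum (O-E)^2/E = 2*(100/30 + 100/70) = 9.5238...
        t = ContingencyTable(("g1", "g2"), ((20, 80), (40, 60)))
        res = chi2_homogeneity(t)
        assert res.statistic == pytest.approx(9.5238095, abs=1e-4)
        assert res.df == 1
        assert res.method is Method.CHI2

    def test_zero_row_total_errors(self):
        t = ContingencyTable(("g1", "g2"), ((0, 0), (5, 5)))
        with pytest.raises(ValueError, match="row total"):
            chi2_homogeneity(t)

    def test_2x2_equals_two_proportion_z_squared(self):
        t = ContingencyTable(("g1", "g2"), ((12, 30), (25, 13)))
        res = chi2_homogeneity(t)
        p1, n1 = 12 / 42, 42
        p2, n2 = 25 / 38, 38
        pooled = (12 + 25) / (42 + 38)
        z = (p1 - p2) / np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
        assert res.statistic == pytest.approx(z**2, rel=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.tuples(st.integers(0, 40), st.integers(0, 40)).filter(
                lambda r: sum(r) > 0
            ),
            min_size=2,
            max_size=6,
        ),
        st.randoms(use_true_random=False),
    )
    def test_statistic_invariant_under_row_permutation(self, rows, rnd):
        if sum(r[0] for r in rows) == 0 or sum(r[1] for r in rows) == 0:
            return
        labels = tuple(f"g{i}" for i in range(len(rows)))
        base = chi2_homogeneity(ContingencyTable(labels, tuple(rows)))
        perm = list(range(len(rows)))
        rnd.shuffle(perm)
        shuffled = chi2_homogeneity(
            ContingencyTable(
                tuple(labels[i] for i in perm), tuple(tuple(rows[i]) for i in perm)
            )
        )
        assert shuffled.statistic == pytest.approx(base.statistic, rel=1e-12)


class TestFisherExact:
    def test_symmetric_table_p_one(self):
        res = fisher_exact_2x2(ContingencyTable(("g1", "g2"), ((1, 1), (1, 1))))
        assert res.p_raw == pytest.approx(1.0)
        assert res.method is Method.FISHER

    def test_perfect_separation_five_by_five(self):
        res = fisher_exact_2x2(ContingencyTable(("g1", "g2"), ((0, 5), (5, 0))))
        assert res.p_raw == pytest.approx(2 / 252, abs=1e-15)

    def test_against_enumeration_oracle_example(self):
        res = fisher_exact_2x2(ContingencyTable(("g1", "g2"), ((5, 0), (1, 4))))
        assert res.p_raw == pytest.approx(fisher_oracle(5, 0, 1, 4), abs=1e-15)

    def test_statistic_is_observed_point_probability(self):
        res = fisher_exact_2x2(ContingencyTable(("g1", "g2"), ((2, 3), (4, 1))))
        expected = comb(5, 2) * comb(5, 4) / comb(10, 6)
        assert res.statistic == pytest.approx(expected, rel=1e-12)

    @settings(derandomize=True, max_examples=200)
    @given(
        st.integers(0, 15), st.integers(0, 15), st.integers(0, 15), st.integers(0, 15)
    )
    def test_matches_oracle_and_scipy_on_random_tables(self, a, b, c, d):
        if a + b == 0 and c + d == 0:
            return
        res = fisher_exact_2x2(ContingencyTable(("g1", "g2"), ((a, b), (c, d))))
        assert res.p_raw == pytest.approx(fisher_oracle(a, b, c, d), abs=1e-12)
        # independent cross-check against the reference implementation
        _, p_scipy = scipy.stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        assert res.p_raw == pytest.approx(p_scipy, abs=1e-9)


class TestBonferroni:
    def test_ceiling_at_one(self):
        assert bonferroni_adjust([0.3], m=6) == [1.0]

    def test_simple_scaling(self):
        assert bonferroni_adjust([0.01], m=4) == [pytest.approx(0.04)]

    def test_zero_stays_zero(self):
        assert bonferroni_adjust([0.0], m=10) == [0.0]

    def test_m_smaller_than_family_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_adjust([0.1, 0.2, 0.3], m=2)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_adjust([1.5], m=2)

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    def test_order_preserving_and_bounded(self, ps):
        adj = bonferroni_adjust(ps, m=len(ps))
        for raw, a in zip(ps, adj):
            assert raw <= a <= 1.0
        for (r1, a1), (r2, a2) in itertools.combinations(zip(ps, adj), 2):
            if r1 <= r2:
                assert a1 <= a2


def _typed_records(study_type, n, start, share_data=0, share_scripts=0,
                   share_materials=0, with_methods=0):
    """n records of one study type with the first k of each resource shared."""
    recs = []
    for i in range(n):
        overrides = dict(study_type=study_type)
        if i < share_data:
            overrides.update(
                data_statement=AvailabilityStatement.YES_AVAILABLE,
                data_mode=AccessMode.UPON_REQUEST,
                data_accessible=TriState.NO,
            )
        if i < share_scripts:
            overrides.update(
                scripts_statement=AvailabilityStatement.YES_AVAILABLE,
                scripts_mode=AccessMode.UPON_REQUEST,
                scripts_accessible=TriState.NO,
            )
        if i < share_materials:
            overrides.update(
                materials_statement=AvailabilityStatement.YES_AVAILABLE,
                materials_mode=AccessMode.UPON_REQUEST,
                materials_accessible=TriState.NO,
            )
        if i < with_methods:
            overrides.update(
                prereg_statement=PreregStatement.YES,
                prereg_accessible=TriState.YES,
            )
        recs.append(negative_record(article_id=f"{study_type.value}-{start + i}",
                                    **overrides))
    return recs


class TestResourceBattery:
    def test_zero_cell_engages_fisher(self):
        recs = _typed_records(StudyType.CLINICAL_TRIAL, 10, 0,
                              share_data=5, share_scripts=4, share_materials=3,
                              with_methods=2)
        recs += _typed_records(StudyType.LAB_ANIMAL, 10, 100,
                               share_data=5, share_scripts=0, share_materials=3,
                               with_methods=2)
        rs = RecordSet(records=tuple(recs), provenance="battery")
        battery = resource_battery(rs, min_group_size=5)
        by_resource = {pc.resource: pc for pc in battery.pairwise}
        assert by_resource["analysis"].result.method is Method.FISHER
        assert by_resource["data"].result.method is Method.CHI2

    def test_identical_groups_give_unit_p(self):
        recs = _typed_records(StudyType.CLINICAL_TRIAL, 10, 0, share_data=5,
                              share_scripts=5, share_materials=5, with_methods=5)
        recs += _typed_records(StudyType.LAB_ANIMAL, 10, 100, share_data=5,
                               share_scripts=5, share_materials=5, with_methods=5)
        rs = RecordSet(records=tuple(recs), provenance="battery")
        battery = resource_battery(rs, min_group_size=5)
        for pc in battery.pairwise:
            assert pc.result.p_raw == pytest.approx(1.0)
            assert pc.result.p_adjusted == pytest.approx(1.0)

    def test_four_types_yield_24_pairwise_tests(self):
        recs = []
        for j, stype in enumerate(
            (StudyType.CLINICAL_TRIAL, StudyType.CLINICAL_OBSERVATIONAL,
             StudyType.LAB_ANIMAL, StudyType.CASE_STUDY_OR_SERIES)
        ):
            recs += _typed_records(stype, 10, 1000 * j, share_data=3 + j,
                                   share_scripts=2 + j, share_materials=1 + j,
                                   with_methods=2 + j)
        rs = RecordSet(records=tuple(recs), provenance="battery")
        battery = resource_battery(rs, min_group_size=5)
        assert len(battery.pairwise) == 24
        per_resource = {res: 0 for res in ("materials", "methods", "data", "analysis")}
        for pc in battery.pairwise:
            per_resource[pc.resource] += 1
        assert all(v == 6 for v in per_resource.values())

    def test_small_groups_excluded(self):
        recs = _typed_records(StudyType.CLINICAL_TRIAL, 10, 0, share_data=5,
                              share_scripts=3, share_materials=3, with_methods=3)
        recs += _typed_records(StudyType.LAB_ANIMAL, 10, 100, share_data=2,
                               share_scripts=3, share_materials=3, with_methods=3)
        recs += _typed_records(StudyType.CASE_STUDY_OR_SERIES, 3, 200, share_data=1,
                               share_scripts=1, share_materials=1, with_methods=1)
        rs = RecordSet(records=tuple(recs), provenance="battery")
        battery = resource_battery(rs, min_group_size=5)
        assert battery.excluded_types == (StudyType.CASE_STUDY_OR_SERIES.value,)
        assert StudyType.CASE_STUDY_OR_SERIES.value not in battery.study_types

    def test_fewer_than_two_eligible_types_errors(self):
        recs = _typed_records(StudyType.CLINICAL_TRIAL, 10, 0, share_data=5,
                              share_scripts=3, with_methods=3)
        rs = RecordSet(records=tuple(recs), provenance="battery")
        with pytest.raises(ValueError, match=">=2 study types"):
            resource_battery(rs, min_group_size=5)
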