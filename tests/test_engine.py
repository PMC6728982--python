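"""Criterion application engine: proportions, pass/fail, heat map,
discrepancy checks, and the monotonicity/nesting properties."""

from fractions import Fraction

import pytest
from hypothesis import given, settings
import hypothesis.strategies as st

from aeselect import (
    AETable,
    DifferenceRule,
    DiffKind,
    GroupScope,
    SelectionCriterion,
    apply_criterion,
    build_grid,
    check_discrepancies,
    heatmap,
    parse_criterion,
    passes,
    proportion,
)

from conftest import ae_tables


# -- independent brute-force evaluator ----------------------------------------
# Written directly from the prose reading of a criterion: "AEs are reported
# if they occurred in >= T% of <group>, [and at least R times / more
# frequently in the active group than placebo]".  Deliberately structured
# unlike the engine: per-arm percentage dictionaries, explicit branches.


def brute_force_reported(table: AETable, criterion: SelectionCriterion) -> set[str]:
    active = [a for a in table.arms if a.is_active]
    comparator = [a for a in table.arms if not a.is_active]
    reported = set()
    for rec in table.records:
        pct = {a.name: Fraction(rec.counts[a.name], a.n) for a in table.arms}
        act = Fraction(sum(rec.counts[a.name] for a in active), sum(a.n for a in active))
        cmp_ = Fraction(
            sum(rec.counts[a.name] for a in comparator), sum(a.n for a in comparator)
        )
        if criterion.scope is GroupScope.ANY_GROUP:
            meets_threshold = max(pct.values()) >= criterion.threshold
        elif criterion.scope is GroupScope.ACTIVE:
            meets_threshold = act >= criterion.threshold
        else:
            total_with_event = sum(rec.counts.values())
            total_n = sum(a.n for a in table.arms)
            meets_threshold = Fraction(total_with_event, total_n) >= criterion.threshold
        if not meets_threshold:
            continue
        if criterion.diff.kind is DiffKind.NONE:
            reported.add(rec.term)
        elif criterion.diff.kind is DiffKind.HIGHER_ACTIVE:
            if act > cmp_:
                reported.add(rec.term)
        else:
            if cmp_ == 0:
                if act > 0:
                    reported.add(rec.term)
            elif act / cmp_ >= criterion.diff.ratio:
                reported.add(rec.term)
    return reported


# -- proportions ---------------------------------------------------------------


class TestProportion:
    def test_single_arm_proportion(self, fixture_table):
        assert proportion(fixture_table, "dizziness", "gabapentin") == Fraction(20, 100)

    def test_all_combined_pools_every_arm(self, fixture_table):
        assert proportion(fixture_table, "dizziness", GroupScope.ALL_COMBINED) == Fraction(25, 200)

    def test_active_pools_dose_arms(self, three_arm_table):
        assert proportion(three_arm_table, "somnolence", GroupScope.ACTIVE) == Fraction(30, 200)

    def test_active_restricted_to_named_arm(self, three_arm_table):
        p = proportion(three_arm_table, "somnolence", GroupScope.ACTIVE, active_arm="drug_high")
        assert p == Fraction(20, 100)

    def test_errors(self, fixture_table):
        with pytest.raises(KeyError):
            proportion(fixture_table, "insomnia", "gabapentin")
        with pytest.raises(KeyError):
            proportion(fixture_table, "dizziness", "quetiapine")
        with pytest.raises(ValueError, match="ANY_GROUP"):
            proportion(fixture_table, "dizziness", GroupScope.ANY_GROUP)


# -- pass/fail -----------------------------------------------------------------


class TestPasses:
    def test_any_group_threshold(self, fixture_table):
        assert passes(fixture_table, "dizziness", parse_criterion("thr=5%"))

    def test_ratio_rule_fails_on_equal_frequencies(self, fixture_table):
        crit = parse_criterion("thr=5%;scope=active;diff=ratio>=2")
        assert not passes(fixture_table, "headache", crit)  # 6% vs 6%, ratio 1

    def test_zero_comparator_convention(self):
        from aeselect import AERecord, Arm

        t = AETable(
            "Z",
            [Arm("drug", 100, True), Arm("placebo", 100)],
            [AERecord("x", {"drug": 12, "placebo": 0})],
        )
        assert passes(t, "x", parse_criterion("thr=10%;scope=active;diff=ratio>=2"))

    def test_zero_vs_zero_fails_ratio_rule(self):
        # exact 0-vs-0 cannot be stored (all-zero terms are dropped), so the
        # convention is exercised through the rounded-percents switch, where
        # 1/300 in each arm rounds to 0% vs 0%
        from aeselect import AERecord, Arm

        t = AETable(
            "Z",
            [Arm("drug", 300, True), Arm("placebo", 300)],
            [AERecord("x", {"drug": 1, "placebo": 1})],
        )
        crit = parse_criterion("thr=0%;scope=active;diff=ratio>=2")
        # exact: 1/300 vs 1/300 -> ratio 1, fails
        assert not passes(t, "x", crit)
        # rounded to whole percents both become 0: 0-vs-0 fails the ratio clause
        assert not passes(t, "x", crit, rounded_percents=True)

    def test_higher_active_is_strict(self, fixture_table):
        crit = parse_criterion("thr=5%;scope=active;diff=higher")
        assert not passes(fixture_table, "headache", crit)  # tie carries no signal
        assert passes(fixture_table, "dizziness", crit)

    def test_rounded_percents_switch(self):
        from aeselect import AERecord, Arm

        # 14/300 = 4.67% -> rounds to 5%
        t = AETable(
            "R",
            [Arm("drug", 300, True), Arm("placebo", 300)],
            [AERecord("x", {"drug": 14, "placebo": 0})],
        )
        crit = parse_criterion("thr=5%;scope=active")
        assert not passes(t, "x", crit)
        assert passes(t, "x", crit, rounded_percents=True)

    def test_strict_threshold_switch(self, fixture_table):
        crit = parse_criterion("thr=20%")
        assert passes(fixture_table, "dizziness", crit)  # 20% >= 20%
        assert not passes(fixture_table, "dizziness", crit, strict_thresholds=True)


# -- reported sets -------------------------------------------------------------


class TestApplyCriterion:
    @pytest.mark.parametrize(
        "text, expected_terms, expected_pct",
        [
            ("thr=5%;scope=any;diff=none", ("dizziness", "headache"), 50.0),
            ("thr=0%;scope=any;diff=none", ("dizziness", "fatigue", "headache", "nausea"), 100.0),
            ("thr=5%;scope=active;diff=ratio>=2", ("dizziness",), 25.0),
        ],
    )
    def test_fixture_reported_sets(self, fixture_table, text, expected_terms, expected_pct):
        rs = apply_criterion(fixture_table, parse_criterion(text))
        assert rs.terms == expected_terms
        assert rs.percent_reported == pytest.approx(expected_pct)
        assert rs.n_total_terms == 4

    @given(table=ae_tables())
    def test_percent_reported_bounded(self, table):
        rs = apply_criterion(table, parse_criterion("thr=3%;scope=active;diff=higher"))
        assert 0.0 <= rs.percent_reported <= 100.0
        assert set(rs.terms) <= set(table.terms)


# -- properties ----------------------------------------------------------------

_SCOPES = st.sampled_from(list(GroupScope))
_DIFFS = st.sampled_from(
    [DifferenceRule(), DifferenceRule(DiffKind.HIGHER_ACTIVE), DifferenceRule(DiffKind.RATIO_GE, 2)]
)
_PCTS = st.sampled_from([0, 1, 2, 3, 5, 8, 10, 20, 50, 100])


class TestProperties:
    @given(table=ae_tables(), p1=_PCTS, p2=_PCTS, scope=_SCOPES, diff=_DIFFS)
    def test_threshold_monotonicity(self, table, p1, p2, scope, diff):
        lo, hi = sorted([p1, p2])
        t_lo = apply_criterion(table, SelectionCriterion(Fraction(lo, 100), scope, diff))
        t_hi = apply_criterion(table, SelectionCriterion(Fraction(hi, 100), scope, diff))
        assert set(t_hi.terms) <= set(t_lo.terms)

    @given(table=ae_tables(), pct=_PCTS, diff=_DIFFS)
    def test_scope_nesting(self, table, pct, diff):
        """Pooled proportions never exceed the max per-arm proportion."""
        t = Fraction(pct, 100)
        any_set = set(apply_criterion(table, SelectionCriterion(t, GroupScope.ANY_GROUP, diff)).terms)
        act = set(apply_criterion(table, SelectionCriterion(t, GroupScope.ACTIVE, diff)).terms)
        allc = set(apply_criterion(table, SelectionCriterion(t, GroupScope.ALL_COMBINED, diff)).terms)
        assert act <= any_set
        assert allc <= any_set

    @given(table=ae_tables(), pct=_PCTS, scope=_SCOPES, diff=_DIFFS)
    def test_difference_rule_shrinkage(self, table, pct, scope, diff):
        t = Fraction(pct, 100)
        base = set(apply_criterion(table, SelectionCriterion(t, scope, DifferenceRule())).terms)
        with_diff = set(apply_criterion(table, SelectionCriterion(t, scope, diff)).terms)
        assert with_diff <= base

    @settings(max_examples=250)
    @given(table=ae_tables(), pct=_PCTS, scope=_SCOPES, diff=_DIFFS)
    def test_brute_force_oracle_equivalence(self, table, pct, scope, diff):
        crit = SelectionCriterion(Fraction(pct, 100), scope, diff)
        assert set(apply_criterion(table, crit).terms) == brute_force_reported(table, crit)


# -- heat map ------------------------------------------------------------------


class TestHeatmap:
    def test_single_cell(self, fixture_table):
        g = build_grid([Fraction(5, 100)], [GroupScope.ANY_GROUP], [DifferenceRule()])
        hm = heatmap([fixture_table], g)
        assert hm.cells == ((50.0,),)
        assert hm.rows == ("thr=5%;scope=any;diff=none",)
        assert hm.cols == ("T1",)

    def test_boundary_thresholds(self, fixture_table):
        g = build_grid([Fraction(0), Fraction(1)], [GroupScope.ANY_GROUP], [DifferenceRule()])
        hm = heatmap([fixture_table], g)
        assert hm.cells[0] == (100.0,)  # thr=0% reports every stored term
        assert hm.cells[1] == (0.0,)    # no arm reaches 100% incidence

    def test_identical_tables_give_identical_columns(self, fixture_table):
        from aeselect import AETable

        twin = AETable("T2", fixture_table.arms, fixture_table.records)
        g = build_grid(
            [Fraction(p, 100) for p in (1, 5, 10)],
            [GroupScope.ANY_GROUP, GroupScope.ACTIVE],
            [DifferenceRule()],
        )
        hm = heatmap([fixture_table, twin], g)
        for row in hm.cells:
            assert row[0] == row[1]

    def test_cells_decrease_down_threshold_ordering(self, fixture_table, three_arm_table):
        """The red-green gradient: higher thresholds report weakly fewer AEs."""
        from aeselect import observed_grid

        hm = heatmap([fixture_table, three_arm_table], observed_grid())
        by_row = dict(zip(hm.rows, hm.cells))
        for scope in ("any", "active", "all"):
            for diff in ("none", "higher", "ratio>=2"):
                cols = [by_row[f"thr={p}%;scope={scope};diff={diff}"] for p in (1, 2, 3, 5, 10)]
                for col in range(len(hm.cols)):
                    vals = [c[col] for c in cols]
                    assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_annotations_and_frame(self, fixture_table):
        g = build_grid([Fraction(5, 100)], [GroupScope.ANY_GROUP], [DifferenceRule()])
        hm = heatmap([fixture_table], g, annotations={("thr=5%;scope=any;diff=none", "T1")})
        assert ("thr=5%;scope=any;diff=none", "T1") in hm.annotations
        df = hm.to_frame()
        assert df.loc["thr=5%;scope=any;diff=none", "T1"] == 50.0


# -- discrepancy checks --------------------------------------------------------


class TestDiscrepancies:
    def test_exact_reporting_has_no_discrepancies(self, fixture_table):
        crit = parse_criterion("thr=5%")
        rep = check_discrepancies(fixture_table, ["dizziness", "headache"], crit)
        assert rep.under_reported == () and rep.over_included == ()

    def test_under_reported_terms_found(self, fixture_table):
        rep = check_discrepancies(fixture_table, ["headache"], parse_criterion("thr=5%"))
        assert rep.under_reported == ("dizziness",)
        assert rep.over_included == ()

    def test_unknown_reported_terms_flagged(self, fixture_table):
        rep = check_discrepancies(
            fixture_table, ["headache", "insomnia"], parse_criterion("thr=5%")
        )
        assert "insomnia" in rep.over_included
        assert rep.unknown_terms == ("insomnia",)

    def test_lists_are_disjoint(self, fixture_table):
        rep = check_discrepancies(
            fixture_table, ["nausea", "Dizziness"], parse_criterion("thr=5%")
        )
        assert not set(rep.under_reported) & set(rep.over_included)
        # case-insensitive matching: Dizziness satisfies the dizziness requirement
        assert "dizziness" not in {t.lower() for t in rep.under_reported}
        assert rep.over_included == ("nausea",)
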