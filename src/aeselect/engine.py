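"""Apply selection criteria to AE tables.

All incidence comparisons use exact rational arithmetic (``Fraction``), so
20/100 >= 2/100 is decided exactly, never on rounded percentages.  Two
conventions some report authors may have used are exposed as switches,
both off by default:

* ``rounded_percents`` — round each proportion to a whole percent before
  comparing, mimicking authors who thresholded the printed table;
* ``strict_thresholds`` — use ``>`` instead of ``>=`` at the threshold.

Scope semantics for a criterion threshold ``t``:

* ``ANY_GROUP``  — max over single-arm proportions >= t,
* ``ACTIVE``     — pooled active-arm proportion >= t (dose arms pooled by
  default; pass ``active_arm=`` to restrict to one named arm),
* ``ALL_COMBINED`` — all-arms pooled proportion >= t.

Difference rules always compare pooled active vs pooled comparator
incidence.  Zero-comparator convention for the ratio rule: active > 0 vs
comparator 0 passes ("at least r times as frequent" is vacuously exceeded);
0 vs 0 fails (no signal).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

from .ae_tables import AETable, normalize_term
from .criteria import CriterionGrid, DiffKind, GroupScope, SelectionCriterion

__all__ = [
    "ReportedSet",
    "HeatmapMatrix",
    "DiscrepancyReport",
    "proportion",
    "passes",
    "apply_criterion",
    "heatmap",
    "check_discrepancies",
]


def _pooled(table: AETable, term: str, arms) -> Fraction:
    rec = table.record(term)
    num = sum(rec.counts[a.name] for a in arms)
    den = sum(a.n for a in arms)
    return Fraction(num, den)


def proportion(
    table: AETable,
    term: str,
    scope: GroupScope | str,
    *,
    active_arm: str | None = None,
) -> Fraction:
    """Exact incidence proportion of ``term`` in the given scope.

    ``scope`` may be a :class:`GroupScope` or an arm name (per-arm form).
    ``ANY_GROUP`` is not a single number; callers wanting its semantics
    take the max over per-arm proportions.
    """
    if isinstance(scope, str) and not isinstance(scope, GroupScope):
        arm = table.arm(scope)  # raises KeyError for unknown arm
        return Fraction(table.record(term).counts[arm.name], arm.n)
    if scope is GroupScope.ACTIVE:
        arms = _active_arms(table, active_arm)
        return _pooled(table, term, arms)
    if scope is GroupScope.ALL_COMBINED:
        return _pooled(table, term, table.arms)
    raise ValueError(
        "ANY_GROUP has no single proportion; use per-arm form or max over arms"
    )


def _active_arms(table: AETable, active_arm: str | None):
    if active_arm is not None:
        arm = table.arm(active_arm)
        if not arm.is_active:
            raise ValueError(f"arm {active_arm!r} is not flagged active")
        return [arm]
    arms = table.active_arms
    if not arms:
        raise ValueError(f"trial {table.trial_id!r} has no active arm")
    return arms


def _maybe_round(p: Fraction, rounded_percents: bool) -> Fraction:
    if not rounded_percents:
        return p
    # round-half-up to a whole percent, as printed AE tables convention
    pct = p * 100
    return Fraction(int(pct + Fraction(1, 2)), 100)


def passes(
    table: AETable,
    term: str,
    criterion: SelectionCriterion,
    *,
    rounded_percents: bool = False,
    strict_thresholds: bool = False,
    active_arm: str | None = None,
) -> bool:
    """Whether one AE term meets a criterion in one trial."""
    rec = table.record(term)  # raises KeyError for unknown term

    def ge(p: Fraction, t: Fraction) -> bool:
        p = _maybe_round(p, rounded_percents)
        return p > t if strict_thresholds else p >= t

    t = criterion.threshold
    if criterion.scope is GroupScope.ANY_GROUP:
        thr_ok = any(ge(Fraction(rec.counts[a.name], a.n), t) for a in table.arms)
    elif criterion.scope is GroupScope.ACTIVE:
        thr_ok = ge(_pooled(table, term, _active_arms(table, active_arm)), t)
    else:
        thr_ok = ge(_pooled(table, term, table.arms), t)
    if not thr_ok:
        return False

    if criterion.diff.kind is DiffKind.NONE:
        return True
    p_act = _maybe_round(
        _pooled(table, term, _active_arms(table, active_arm)), rounded_percents
    )
    p_cmp = _maybe_round(_pooled(table, term, table.comparator_arms), rounded_percents)
    if criterion.diff.kind is DiffKind.HIGHER_ACTIVE:
        return p_act > p_cmp
    # RATIO_GE: zero-comparator convention
    if p_cmp == 0:
        return p_act > 0
    return p_act >= criterion.diff.ratio * p_cmp


@dataclass(frozen=True)
class ReportedSet:
    """AE terms of one trial passing one criterion — one heat-map cell."""

    trial_id: str
    criterion: SelectionCriterion
    terms: tuple[str, ...]
    n_total_terms: int

    @property
    def percent_reported(self) -> float:
        if self.n_total_terms == 0:
            return 0.0
        return 100.0 * len(self.terms) / self.n_total_terms


def apply_criterion(
    table: AETable,
    criterion: SelectionCriterion,
    **options,
) -> ReportedSet:
    """Evaluate a criterion on every stored term of a trial.

    The percent-reported denominator is the number of distinct AE types
    stored in the table (terms with >=1 affected participant), i.e. the
    complete CSR listing.
    """
    kept = sorted(
        (r.term for r in table.records if passes(table, r.term, criterion, **options)),
        key=normalize_term,
    )
    return ReportedSet(table.trial_id, criterion, tuple(kept), table.n_terms)


@dataclass(frozen=True)
class HeatmapMatrix:
    """Percent-of-AEs-reported for every (criterion, trial) pair.

    Rows follow grid order, columns the given trial order.  ``annotations``
    marks (criterion label, trial id) pairs actually used by at least one
    source — the black-outlined squares of the published figure.
    """

    rows: tuple[str, ...]                      # criterion labels
    cols: tuple[str, ...]                      # trial ids
    cells: tuple[tuple[float, ...], ...]       # rows x cols percents
    annotations: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    def cell(self, criterion_label: str, trial_id: str) -> float:
        return self.cells[self.rows.index(criterion_label)][self.cols.index(trial_id)]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [list(r) for r in self.cells], index=list(self.rows), columns=list(self.cols)
        )


def heatmap(
    tables: list[AETable],
    grid: CriterionGrid,
    annotations: set[tuple[str, str]] | None = None,
    **options,
) -> HeatmapMatrix:
    """Apply every grid criterion to every trial table."""
    if not tables:
        raise ValueError("need at least one table")
    ids = [t.trial_id for t in tables]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate trial ids")
    cells = []
    for crit in grid:
        row = []
        for table in tables:
            try:
                row.append(apply_criterion(table, crit, **options).percent_reported)
            except ValueError as e:
                raise ValueError(
                    f"criterion {crit.label!r} inapplicable to trial "
                    f"{table.trial_id!r}: {e}"
                ) from e
        cells.append(tuple(row))
    return HeatmapMatrix(
        tuple(grid.labels), tuple(ids), tuple(cells), frozenset(annotations or ())
    )


@dataclass(frozen=True)
class DiscrepancyReport:
    """Terms a source should have reported under its stated criterion but
    did not (``under_reported``), and terms it reported although they fail
    the criterion (``over_included``).  Reported terms absent from the full
    table appear in ``over_included`` and again in ``unknown_terms``."""

    under_reported: tuple[str, ...]
    over_included: tuple[str, ...]
    unknown_terms: tuple[str, ...]


def check_discrepancies(
    full: AETable,
    reported_terms: list[str],
    stated: SelectionCriterion,
    **options,
) -> DiscrepancyReport:
    """Compare a source's reported AE list against its stated criterion
    applied to the complete (CSR) table."""
    should = {normalize_term(t): t for t in apply_criterion(full, stated, **options).terms}
    reported = {normalize_term(t): t for t in reported_terms}

    under = sorted(k for k in should if k not in reported)
    over = sorted(k for k in reported if k not in should)
    unknown = sorted(k for k in reported if not full.has_term(k))
    return DiscrepancyReport(
        tuple(should[k] for k in under),
        tuple(reported[k] for k in over),
        tuple(reported[k] for k in unknown),
    )
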