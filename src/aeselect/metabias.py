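"""Selective-reporting bias in AE meta-analysis, quantified by simulation.

The experiment mimics what a systematic reviewer of journal articles can
do.  A drug programme is simulated as k trials sharing true per-arm AE
incidences.  A selection criterion censors each trial down to its
"journal-article view".  For each AE term the pooled risk ratio is then
computed twice with the same fixed-effect Mantel-Haenszel estimator:

* **complete** — over all k trials (the CSR corpus a regulator sees);
* **selective** — only over the trials whose censored report includes the
  term (availability bias: a reviewer cannot pool what was not reported).

Because criteria keep a term exactly when its observed frequency is high
(and, for difference rules, when the active-arm contrast is positive),
conditioning on reporting selects positive noise: under the global null
the selective pooled log-RR is biased upward, and rare AEs vanish
entirely.  Effect magnitudes are simulation outputs, not reproduction
targets; the contract is direction and determinism.

The Mantel-Haenszel pooled risk ratio over strata i is

    RR_MH = [sum_i a_i * n0_i / N_i] / [sum_i c_i * n1_i / N_i],  N_i = n1_i + n0_i

with no continuity correction: zero cells contribute zero to the sums, and
a zero denominator sum makes the estimate undefined (flagged, not patched).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .ae_tables import AETable, normalize_term
from .criteria import SelectionCriterion
from .engine import apply_criterion
from .synthetic import SyntheticConfig, draw_truth, simulate_trials

__all__ = [
    "TwoByTwo",
    "TermBias",
    "BiasResult",
    "extract_two_by_two",
    "mh_pooled_rr",
    "simulate_reporting",
    "bias_experiment",
]


@dataclass(frozen=True)
class TwoByTwo:
    """Pooled active vs pooled comparator 2x2 for one term in one trial."""

    a: int       # active participants with the event
    n1: int      # active total
    c: int       # comparator participants with the event
    n0: int      # comparator total
    absent: bool = False  # term not stored in the trial's table

    def __post_init__(self) -> None:
        if not (0 <= self.a <= self.n1 and 0 <= self.c <= self.n0):
            raise ValueError(f"invalid 2x2: a={self.a}/{self.n1}, c={self.c}/{self.n0}")


def extract_two_by_two(table: AETable, term: str) -> TwoByTwo:
    """Pool active arms vs comparator arms into one 2x2 for a term.

    A term absent from the table yields a zero-event 2x2 flagged
    ``absent`` (the arm totals are still informative denominators).
    """
    n1 = sum(a.n for a in table.active_arms)
    n0 = sum(a.n for a in table.comparator_arms)
    if not table.has_term(term):
        return TwoByTwo(0, n1, 0, n0, absent=True)
    rec = table.record(term)
    a = sum(rec.counts[x.name] for x in table.active_arms)
    c = sum(rec.counts[x.name] for x in table.comparator_arms)
    return TwoByTwo(a, n1, c, n0)


def mh_pooled_rr(strata: Sequence[TwoByTwo]) -> float | None:
    """Fixed-effect Mantel-Haenszel pooled risk ratio.

    Returns ``None`` when the denominator sum is zero (no comparator
    events in any stratum), rather than applying a continuity correction.
    """
    if not strata:
        raise ValueError("need at least one stratum")
    num = 0.0
    den = 0.0
    for s in strata:
        big_n = s.n1 + s.n0
        num += s.a * s.n0 / big_n
        den += s.c * s.n1 / big_n
    if den == 0.0:
        return None
    return num / den


def simulate_reporting(
    tables: list[AETable], criterion: SelectionCriterion, **options
) -> list[AETable]:
    """Censor each trial to the terms passing the criterion — the
    journal-article view of the programme."""
    return [t.subset(apply_criterion(t, criterion, **options).terms) for t in tables]


@dataclass(frozen=True)
class TermBias:
    """Per-term summary, averaged over Monte-Carlo replicates."""

    term: str
    true_log_rr: float
    elevated: bool
    mean_log_rr_complete: float      # nan if never defined
    mean_log_rr_selective: float     # nan if never reported
    mean_n_trials_reporting: float
    frac_reps_reported: float        # fraction of replicates with >=1 reporting trial


@dataclass(frozen=True)
class BiasResult:
    """One criterion's selective-reporting experiment summary.

    ``mean_bias_selective_vs_true`` averages (selective pooled log-RR minus
    true log-RR) over terms reported at least once, then over replicates.
    ``mean_selective_minus_complete`` is the same contrast against the
    complete-corpus estimate — exactly zero when the criterion censors
    nothing.
    """

    criterion: SelectionCriterion
    n_trials: int
    n_reps: int
    terms: tuple[TermBias, ...] = field(repr=False)
    mean_bias_selective_vs_true: float
    mean_selective_minus_complete: float
    mean_selective_log_rr: float
    frac_elevated_ever_reported: float
    frac_terms_never_reported: float
    # per-replicate mean selective pooled log-RR over defined terms
    # (nan for replicates where no term has a defined selective estimate)
    rep_mean_selective_log_rr: tuple[float, ...] = field(default=(), repr=False)


def _log_or_nan(x: float | None) -> float:
    if x is None or x <= 0.0:
        return math.nan
    return math.log(x)


def bias_experiment(
    config: SyntheticConfig,
    k_trials: int,
    criteria: Sequence[SelectionCriterion],
    reps: int,
    master_seed: int,
    **options,
) -> list[BiasResult]:
    """Monte-Carlo experiment: how does criterion-based censoring distort
    the pooled risk ratio, and which AEs disappear?

    The true incidence structure is drawn once from ``master_seed``; each
    replicate resamples trial counts, censors each trial with each
    criterion, and meta-analyses every term both ways.  Per-term selective
    estimates pool only the trials reporting the term; a term reported
    nowhere in a replicate contributes no selective estimate there.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    truth = draw_truth(config, master_seed)
    true_lrr = truth.true_log_rr(config)
    n_terms = len(truth.terms)
    term_index = {normalize_term(t): j for j, t in enumerate(truth.terms)}

    # accumulators: [criterion][term]
    k_crit = len(criteria)
    sel_sum = np.zeros((k_crit, n_terms))
    sel_cnt = np.zeros((k_crit, n_terms))
    cmp_sum = np.zeros((k_crit, n_terms))       # complete, where selective defined
    comp_sum = np.zeros(n_terms)
    comp_cnt = np.zeros(n_terms)
    n_rep_sum = np.zeros((k_crit, n_terms))
    rep_reported = np.zeros((k_crit, n_terms))  # replicates with >=1 reporting trial
    ever_reported = np.zeros((k_crit, n_terms), dtype=bool)
    rep_means: list[list[float]] = [[] for _ in range(k_crit)]

    for rep in range(reps):
        tables = simulate_trials(
            config, k_trials, master_seed, truth=truth, replicate=rep
        )
        strata_all = [[extract_two_by_two(t, term) for t in tables] for term in truth.terms]
        complete = np.array(
            [_log_or_nan(mh_pooled_rr(s)) for s in strata_all]
        )
        defined = ~np.isnan(complete)
        comp_sum[defined] += complete[defined]
        comp_cnt[defined] += 1

        for ci, crit in enumerate(criteria):
            reported_by_trial = [
                {normalize_term(t) for t in apply_criterion(tab, crit, **options).terms}
                for tab in tables
            ]
            this_rep_sels: list[float] = []
            for j, term in enumerate(truth.terms):
                key = normalize_term(term)
                idx = [ti for ti, rep_set in enumerate(reported_by_trial) if key in rep_set]
                n_rep_sum[ci, j] += len(idx)
                if not idx:
                    continue
                rep_reported[ci, j] += 1
                ever_reported[ci, j] = True
                sel = _log_or_nan(mh_pooled_rr([strata_all[j][ti] for ti in idx]))
                if not math.isnan(sel):
                    sel_sum[ci, j] += sel
                    sel_cnt[ci, j] += 1
                    this_rep_sels.append(sel)
                    if not math.isnan(complete[j]):
                        cmp_sum[ci, j] += complete[j]
            rep_means[ci].append(
                float(np.mean(this_rep_sels)) if this_rep_sels else math.nan
            )

    results = []
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_complete = np.where(comp_cnt > 0, comp_sum / np.maximum(comp_cnt, 1), np.nan)
        for ci, crit in enumerate(criteria):
            mean_sel = np.where(sel_cnt[ci] > 0, sel_sum[ci] / np.maximum(sel_cnt[ci], 1), np.nan)
            mean_cmp_paired = np.where(
                sel_cnt[ci] > 0, cmp_sum[ci] / np.maximum(sel_cnt[ci], 1), np.nan
            )
            term_rows = tuple(
                TermBias(
                    term=truth.terms[j],
                    true_log_rr=float(true_lrr[j]),
                    elevated=bool(truth.elevated[j]),
                    mean_log_rr_complete=float(mean_complete[j]),
                    mean_log_rr_selective=float(mean_sel[j]),
                    mean_n_trials_reporting=float(n_rep_sum[ci, j] / reps),
                    frac_reps_reported=float(rep_reported[ci, j] / reps),
                )
                for j in range(n_terms)
            )
            have_sel = sel_cnt[ci] > 0
            finite_true = np.isfinite(true_lrr)
            bias_mask = have_sel & finite_true
            mean_bias = float(np.nanmean(mean_sel[bias_mask] - true_lrr[bias_mask])) if bias_mask.any() else math.nan
            smc = (
                float(np.nanmean(mean_sel[have_sel] - mean_cmp_paired[have_sel]))
                if have_sel.any()
                else math.nan
            )
            elev = truth.elevated
            results.append(
                BiasResult(
                    criterion=crit,
                    n_trials=k_trials,
                    n_reps=reps,
                    terms=term_rows,
                    mean_bias_selective_vs_true=mean_bias,
                    mean_selective_minus_complete=smc,
                    mean_selective_log_rr=float(np.nanmean(mean_sel[have_sel])) if have_sel.any() else math.nan,
                    frac_elevated_ever_reported=float(ever_reported[ci][elev].mean()) if elev.any() else math.nan,
                    frac_terms_never_reported=float((~ever_reported[ci]).mean()),
                    rep_mean_selective_log_rr=tuple(rep_means[ci]),
                )
            )
    return results
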