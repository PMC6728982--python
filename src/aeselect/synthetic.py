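"""Synthetic trials with the structure of non-systematically collected AEs.

Spontaneous AE collection yields many distinct event types whose background
incidence spans orders of magnitude — a handful of common complaints
(headache, nausea) and a long tail of rare ones.  The generator draws a
per-term comparator-arm incidence from a long-tailed law, elevates a
configurable fraction of terms in the active arm(s) by a common risk
ratio, and samples per-arm participant counts independently as binomials.
Terms with zero affected participants in every arm are dropped, mirroring
that a CSR listing only contains events that actually occurred.

Seeding contract: every trial draws from its own PRNG stream derived
deterministically from ``(master_seed, replicate, trial_index)`` via
``numpy.random.SeedSequence`` spawn keys, so adding trials or replicates
never perturbs earlier ones.  The shared true-incidence structure uses its
own stream derived from the master seed alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .ae_tables import AERecord, AETable, Arm

__all__ = ["RateLaw", "SyntheticConfig", "TrialTruth", "draw_truth", "simulate_trial", "simulate_trials"]


@dataclass(frozen=True)
class RateLaw:
    """Distribution of per-term background (comparator-arm) incidence.

    ``log_uniform(lo, hi)``: log10-uniform on [lo, hi] — equal mass per
    decade, the conventional sketch of an AE term-frequency spectrum.
    ``power_law(alpha, min_rate)``: Pareto with density ∝ p^-alpha on
    [min_rate, 1].
    """

    kind: Literal["log_uniform", "power_law"] = "log_uniform"
    lo: float = 5e-4
    hi: float = 0.2
    alpha: float = 1.5
    min_rate: float = 1e-4

    def __post_init__(self) -> None:
        if self.kind == "log_uniform":
            if not (0 < self.lo <= self.hi <= 1):
                raise ValueError(f"need 0 < lo <= hi <= 1, got ({self.lo}, {self.hi})")
        elif self.kind == "power_law":
            if not (0 < self.min_rate < 1):
                raise ValueError(f"min_rate must be in (0, 1), got {self.min_rate}")
            if self.alpha <= 1:
                raise ValueError(f"alpha must be > 1, got {self.alpha}")
        else:
            raise ValueError(f"unknown rate law {self.kind!r}")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.kind == "log_uniform":
            lo, hi = math.log10(self.lo), math.log10(self.hi)
            return np.power(10.0, rng.uniform(lo, hi, size))
        # Pareto truncated at 1 via inverse CDF
        u = rng.uniform(0, 1, size)
        a1 = 1.0 - self.alpha
        lo_pow = self.min_rate ** a1
        return np.clip((lo_pow + u * (1.0 ** a1 - lo_pow)) ** (1.0 / a1), None, 1.0)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters for one simulated drug programme.

    ``n_per_arm`` gives the safety-population size of each arm in order;
    ``active_flags`` marks test-intervention arms (default: first arm
    active, rest comparator).  ``elevated_fraction`` of the ``n_terms``
    terms get active-arm incidence ``min(1, risk_ratio * p)``.
    """

    n_per_arm: tuple[int, ...] = (200, 200)
    n_terms: int = 300
    rate_law: RateLaw = field(default_factory=RateLaw)
    elevated_fraction: float = 0.1
    risk_ratio: float = 2.0
    active_flags: tuple[bool, ...] | None = None
    arm_names: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_terms < 1:
            raise ValueError("n_terms must be >= 1")
        if not 0 <= self.elevated_fraction <= 1:
            raise ValueError("elevated_fraction must be in [0, 1]")
        if self.risk_ratio <= 0:
            raise ValueError("risk_ratio must be positive")
        if any(n < 1 for n in self.n_per_arm) or len(self.n_per_arm) < 2:
            raise ValueError("need >=2 arms with n >= 1")
        flags = self.active_flags
        if flags is None:
            flags = (True,) + (False,) * (len(self.n_per_arm) - 1)
        if len(flags) != len(self.n_per_arm):
            raise ValueError("active_flags length mismatch")
        if not any(flags) or all(flags):
            raise ValueError("need at least one active and one comparator arm")
        object.__setattr__(self, "active_flags", tuple(bool(f) for f in flags))
        names = self.arm_names
        if names is None:
            n_act = n_cmp = 0
            out = []
            for f in flags:
                if f:
                    n_act += 1
                    out.append("active" if sum(flags) == 1 else f"active_{n_act}")
                else:
                    n_cmp += 1
                    out.append("placebo" if len(flags) - sum(flags) == 1 else f"placebo_{n_cmp}")
            names = tuple(out)
        if len(names) != len(self.n_per_arm) or len(set(names)) != len(names):
            raise ValueError("arm_names must be unique, one per arm")
        object.__setattr__(self, "arm_names", tuple(names))

    def arms(self) -> list[Arm]:
        return [
            Arm(name, n, flag)
            for name, n, flag in zip(self.arm_names, self.n_per_arm, self.active_flags)
        ]


@dataclass(frozen=True)
class TrialTruth:
    """Ground truth attached to simulated tables.

    ``incidence[arm_index, term_index]`` is the true per-arm event
    probability; ``elevated`` flags terms whose active-arm risk is raised.
    """

    terms: tuple[str, ...]
    incidence: np.ndarray           # shape (n_arms, n_terms)
    elevated: np.ndarray            # bool, shape (n_terms,)

    @property
    def n_elevated(self) -> int:
        return int(self.elevated.sum())

    def true_log_rr(self, config: SyntheticConfig) -> np.ndarray:
        """Per-term true log risk ratio, pooled active vs pooled comparator."""
        act = [i for i, f in enumerate(config.active_flags) if f]
        cmp_ = [i for i, f in enumerate(config.active_flags) if not f]
        n = np.asarray(config.n_per_arm, dtype=float)
        p_act = (self.incidence[act] * n[act, None]).sum(0) / n[act].sum()
        p_cmp = (self.incidence[cmp_] * n[cmp_, None]).sum(0) / n[cmp_].sum()
        with np.errstate(divide="ignore"):
            return np.log(p_act) - np.log(p_cmp)


def _term_names(n_terms: int) -> tuple[str, ...]:
    width = max(4, len(str(n_terms)))
    return tuple(f"ae_{i:0{width}d}" for i in range(1, n_terms + 1))


def draw_truth(config: SyntheticConfig, master_seed: int | None = None) -> TrialTruth:
    """Draw the shared true incidence structure for one drug programme.

    The first ``ceil(elevated_fraction * n_terms)`` terms (in term order)
    are elevated; term order itself is random in no meaningful way, so this
    is equivalent to a random subset and keeps the labelling reproducible.
    """
    seed = config.seed if master_seed is None else master_seed
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))
    p_bg = config.rate_law.sample(rng, config.n_terms)
    n_elev = math.ceil(config.elevated_fraction * config.n_terms)
    elevated = np.zeros(config.n_terms, dtype=bool)
    elevated[:n_elev] = True

    flags = np.asarray(config.active_flags)
    incidence = np.tile(p_bg, (len(config.n_per_arm), 1))
    p_act = np.where(elevated, np.minimum(1.0, config.risk_ratio * p_bg), p_bg)
    incidence[flags] = p_act
    return TrialTruth(_term_names(config.n_terms), incidence, elevated)


def _sample_table(
    config: SyntheticConfig, truth: TrialTruth, trial_id: str, rng: np.random.Generator
) -> AETable:
    n = np.asarray(config.n_per_arm)
    counts = rng.binomial(n[:, None], truth.incidence)  # (n_arms, n_terms)
    observed = counts.sum(0) > 0
    records = [
        AERecord(term, {name: int(c) for name, c in zip(config.arm_names, counts[:, j])})
        for j, term in enumerate(truth.terms)
        if observed[j]
    ]
    table = AETable(trial_id, config.arms(), records)
    table.truth = truth  # ground truth rides along for experiments
    return table


def simulate_trial(
    config: SyntheticConfig,
    trial_id: str = "sim_trial",
    *,
    truth: TrialTruth | None = None,
    trial_index: int = 0,
    replicate: int = 0,
    master_seed: int | None = None,
) -> AETable:
    """Simulate one trial; fully reproducible from the config seed.

    With the same config and seed the same table is returned every time.
    Pass ``truth`` (from :func:`draw_truth`) to resample counts under a
    fixed incidence structure.
    """
    seed = config.seed if master_seed is None else master_seed
    if truth is None:
        truth = draw_truth(config, seed)
    rng = np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(1, replicate, trial_index))
    )
    return _sample_table(config, truth, trial_id, rng)


def simulate_trials(
    config: SyntheticConfig,
    k: int,
    master_seed: int | None = None,
    *,
    truth: TrialTruth | None = None,
    replicate: int = 0,
) -> list[AETable]:
    """k independent trials of the same drug: one shared truth, independent counts."""
    if k < 1:
        raise ValueError("k must be >= 1")
    seed = config.seed if master_seed is None else master_seed
    if truth is None:
        truth = draw_truth(config, seed)
    return [
        simulate_trial(
            config,
            f"sim_trial_{i + 1:03d}",
            truth=truth,
            trial_index=i,
            replicate=replicate,
            master_seed=seed,
        )
        for i in range(k)
    ]


def expected_stored_terms(config: SyntheticConfig, truth: TrialTruth) -> tuple[float, float]:
    """Analytic mean and SD of the stored-term count of one simulated trial.

    A term is stored iff at least one participant in any arm has the
    event: retention probability q_t = 1 - prod_arms (1 - p_arm)^n_arm.
    The count is a sum of independent Bernoullis, so the mean is sum(q)
    and the variance sum(q (1 - q)).
    """
    n = np.asarray(config.n_per_arm, dtype=float)
    q = 1.0 - np.prod((1.0 - truth.incidence) ** n[:, None], axis=0)
    return float(q.sum()), float(np.sqrt((q * (1.0 - q)).sum()))
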