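"""Formal representation of AE selection criteria.

A selection criterion decides which AE types from a trial appear in a
report.  It has three components:

1. a **numerical threshold** — a minimum incidence proportion (e.g. ">=2%"),
2. a **participant-group scope** — whose incidence is thresholded: any
   single arm, the (pooled) active arm(s), or all arms combined,
3. an optional **difference-between-groups rule** — the active-arm
   incidence must exceed the comparator's, either strictly or by a factor
   (e.g. "at least twice as frequent").

Criteria are written in a compact DSL::

    thr=<number>%[;scope=<any|active|all>][;diff=<none|higher|ratio>=<r>>]

e.g. ``thr=2%;scope=active;diff=ratio>=2``.  Omitted scope defaults to
``any``, omitted diff to ``none``.  ``render`` is the canonical inverse of
``parse_criterion``: ``parse_criterion(c.label) == c`` for every criterion.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from enum import Enum
from fractions import Fraction
from typing import Iterable, Sequence

__all__ = [
    "GroupScope",
    "DiffKind",
    "DifferenceRule",
    "SelectionCriterion",
    "CriterionGrid",
    "parse_criterion",
    "build_grid",
    "observed_components",
    "observed_grid",
]


class CriterionParseError(ValueError):
    """Malformed criterion DSL text; carries the offending position."""

    def __init__(self, message: str, position: int = 0):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class GroupScope(Enum):
    """Participant group whose AE proportion is thresholded."""

    ANY_GROUP = "any"      # max over single arms
    ACTIVE = "active"      # pooled test-intervention arm(s)
    ALL_COMBINED = "all"   # all arms pooled

    def __str__(self) -> str:
        return self.value


class DiffKind(Enum):
    NONE = "none"
    HIGHER_ACTIVE = "higher"
    RATIO_GE = "ratio"

    def __str__(self) -> str:
        return self.value


def _as_fraction(x) -> Fraction:
    """Exact conversion; floats go through their shortest decimal repr so
    0.05 means exactly 5/100."""
    if isinstance(x, float):
        return Fraction(repr(x))
    return Fraction(x)


def _fmt_number(x: Fraction) -> str:
    """Shortest decimal rendering of an exact fraction (falls back to a/b)."""
    if x.denominator == 1:
        return str(x.numerator)
    f = float(x)
    if _as_fraction(f) == x:
        return repr(f)
    return f"{x.numerator}/{x.denominator}"


@dataclass(frozen=True)
class DifferenceRule:
    """Between-group requirement on pooled active vs pooled comparator incidence."""

    kind: DiffKind = DiffKind.NONE
    ratio: Fraction | None = None

    def __post_init__(self) -> None:
        if self.kind is DiffKind.RATIO_GE:
            if self.ratio is None:
                raise ValueError("RATIO_GE requires a ratio")
            object.__setattr__(self, "ratio", _as_fraction(self.ratio))
            if self.ratio <= 1:
                raise ValueError(f"ratio must be > 1, got {self.ratio}")
        elif self.ratio is not None:
            raise ValueError(f"{self.kind} takes no ratio")

    def render(self) -> str:
        if self.kind is DiffKind.RATIO_GE:
            return f"ratio>={_fmt_number(self.ratio)}"
        return self.kind.value


@dataclass(frozen=True)
class SelectionCriterion:
    """One combined selection criterion: threshold + scope + difference rule.

    The threshold is stored as an exact :class:`~fractions.Fraction`
    proportion in [0, 1] (0.02 for ">=2%"); comparisons downstream are done
    in exact rational arithmetic.
    """

    threshold: Fraction
    scope: GroupScope = GroupScope.ANY_GROUP
    diff: DifferenceRule = DifferenceRule()

    def __post_init__(self) -> None:
        t = _as_fraction(self.threshold)
        if not 0 <= t <= 1:
            raise ValueError(f"threshold must be in [0, 1], got {t}")
        object.__setattr__(self, "threshold", t)

    @property
    def label(self) -> str:
        """Canonical DSL rendering; ``parse_criterion(label)`` round-trips."""
        return (
            f"thr={_fmt_number(self.threshold * 100)}%"
            f";scope={self.scope}"
            f";diff={self.diff.render()}"
        )

    def __str__(self) -> str:
        return self.label


_THR_RE = re.compile(r"^thr=([0-9]+(?:\.[0-9]+)?|[0-9]+/[0-9]+)%$")
_SCOPE_RE = re.compile(r"^scope=(any|active|all)$")
_DIFF_RE = re.compile(r"^diff=(none|higher|ratio>=([0-9]+(?:\.[0-9]+)?|[0-9]+/[0-9]+))$")


def parse_criterion(text: str) -> SelectionCriterion:
    """Parse the criterion DSL into a canonical :class:`SelectionCriterion`."""
    parts = [p.strip() for p in text.strip().split(";")]
    if not parts or not parts[0]:
        raise CriterionParseError("empty criterion", 0)

    pos = 0
    m = _THR_RE.match(parts[0])
    if not m:
        raise CriterionParseError(f"expected 'thr=<number>%', got {parts[0]!r}", pos)
    threshold = Fraction(m.group(1)) / 100
    if threshold > 1:
        raise CriterionParseError(f"threshold {m.group(1)}% exceeds 100%", pos)

    scope = GroupScope.ANY_GROUP
    diff = DifferenceRule()
    seen = set()
    for part in parts[1:]:
        pos = text.find(part)
        if not part:
            raise CriterionParseError("empty clause", pos)
        key = part.split("=", 1)[0]
        if key in seen:
            raise CriterionParseError(f"duplicate clause {key!r}", pos)
        seen.add(key)
        if key == "scope":
            m = _SCOPE_RE.match(part)
            if not m:
                raise CriterionParseError(f"expected scope any|active|all, got {part!r}", pos)
            scope = GroupScope(m.group(1))
        elif key == "diff":
            m = _DIFF_RE.match(part)
            if not m:
                raise CriterionParseError(
                    f"expected diff none|higher|ratio>=<r>, got {part!r}", pos
                )
            if m.group(1) == "none":
                diff = DifferenceRule(DiffKind.NONE)
            elif m.group(1) == "higher":
                diff = DifferenceRule(DiffKind.HIGHER_ACTIVE)
            else:
                ratio = Fraction(m.group(2))
                if ratio <= 1:
                    raise CriterionParseError(f"ratio must be > 1, got {ratio}", pos)
                diff = DifferenceRule(DiffKind.RATIO_GE, ratio)
        else:
            raise CriterionParseError(f"unknown clause {key!r}", pos)
    return SelectionCriterion(threshold, scope, diff)


@dataclass(frozen=True)
class CriterionGrid:
    """Cross-product of component lists, in deterministic threshold-major order."""

    thresholds: tuple[Fraction, ...]
    scopes: tuple[GroupScope, ...]
    diffs: tuple[DifferenceRule, ...]
    criteria: tuple[SelectionCriterion, ...]

    def __len__(self) -> int:
        return len(self.criteria)

    def __iter__(self):
        return iter(self.criteria)

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.criteria]


def build_grid(
    thresholds: Sequence,
    scopes: Sequence[GroupScope],
    diffs: Sequence[DifferenceRule],
) -> CriterionGrid:
    """Cross every threshold with every scope and difference rule.

    Order is threshold-major (in the given threshold order), then scope,
    then diff — stable across runs and platforms.
    """
    thr = tuple(_as_fraction(t) for t in thresholds)
    scp = tuple(scopes)
    dif = tuple(diffs)
    for name, lst in (("thresholds", thr), ("scopes", scp), ("diffs", dif)):
        if not lst:
            raise ValueError(f"empty component list: {name}")
        if len(set(lst)) != len(lst):
            raise ValueError(f"duplicate entries in {name}")
    criteria = tuple(
        SelectionCriterion(t, s, d) for t, s, d in itertools.product(thr, scp, dif)
    )
    return CriterionGrid(thr, scp, dif, criteria)


def observed_components() -> tuple[list[Fraction], list[GroupScope], list[DifferenceRule]]:
    """The component sets observed across gabapentin and quetiapine sources.

    Five numerical thresholds (1%, 2%, 3%, 5% from gabapentin sources, 5%
    and 10% from quetiapine sources), all three participant-group scopes,
    and three difference rules (none, strictly higher in the active group,
    at least twice as high in the active group).  Crossing them yields the
    45 combined criteria applied throughout the analysis.
    """
    thresholds = [Fraction(p, 100) for p in (1, 2, 3, 5, 10)]
    scopes = [GroupScope.ANY_GROUP, GroupScope.ACTIVE, GroupScope.ALL_COMBINED]
    diffs = [
        DifferenceRule(DiffKind.NONE),
        DifferenceRule(DiffKind.HIGHER_ACTIVE),
        DifferenceRule(DiffKind.RATIO_GE, Fraction(2)),
    ]
    return thresholds, scopes, diffs


def observed_grid() -> CriterionGrid:
    """The 45-criterion grid built from :func:`observed_components`."""
    return build_grid(*observed_components())
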