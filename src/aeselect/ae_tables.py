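"""Per-arm adverse-event frequency tables.

The central object is :class:`AETable`: for one randomized trial, the
number of participants in each arm who experienced at least one event of
each distinct adverse-event (AE) type.  Counts are participants, never
events — a participant with three episodes of dizziness contributes 1 to
the "dizziness" count.  A complete table (every observed AE type, no
selection applied) plays the role of a clinical study report (CSR); public
sources typically contain a censored subset of it.

Two plain-text serializations are supported:

* ``csv_long`` — header ``trial_id,arm,n,is_active,ae_term,count``, one row
  per (arm, term).  A row with an empty ``ae_term`` declares an arm without
  contributing a count (needed for tables with no records).
* ``json`` — one object per trial mirroring the dataclass fields.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = ["Arm", "AERecord", "AETable", "read_table", "write_table", "normalize_term"]

CSV_COLUMNS = ["trial_id", "arm", "n", "is_active", "ae_term", "count"]


class ValidationError(ValueError):
    """A table violates a structural invariant."""


class SchemaError(ValueError):
    """A file does not match the expected serialization schema."""


def normalize_term(term: str) -> str:
    """Normalization key for AE-term uniqueness: collapse whitespace, casefold.

    Original casing is preserved everywhere else; no medical coding
    (MedDRA/WHO-ART) is applied.
    """
    return " ".join(term.split()).casefold()


@dataclass(frozen=True)
class Arm:
    """One trial arm: name, safety-population size, and active-intervention flag."""

    name: str
    n: int
    is_active: bool = False

    def __post_init__(self) -> None:
        if not self.name or not str(self.name).strip():
            raise ValidationError("arm name must be non-empty")
        if int(self.n) < 1:
            raise ValidationError(f"arm {self.name!r}: n must be >= 1, got {self.n}")
        object.__setattr__(self, "n", int(self.n))
        object.__setattr__(self, "is_active", bool(self.is_active))


@dataclass(frozen=True)
class AERecord:
    """Participants with >=1 event of one AE type, keyed by arm name."""

    term: str
    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        if not self.term or not normalize_term(self.term):
            raise ValidationError("AE term must be non-empty")
        counts = {str(a): int(c) for a, c in dict(self.counts).items()}
        for arm, c in counts.items():
            if c < 0:
                raise ValidationError(f"term {self.term!r}, arm {arm!r}: negative count {c}")
        object.__setattr__(self, "counts", counts)


@dataclass
class AETable:
    """All AE types observed in one trial, with per-arm participant counts.

    Invariants enforced at construction: >=2 arms with unique names, at
    least one active and one non-active arm; terms unique after whitespace/
    case normalization; every record carries a count for every arm (missing
    arms are filled with 0); counts never exceed the arm size; every stored
    term has at least one affected participant somewhere.
    """

    trial_id: str
    arms: list[Arm]
    records: list[AERecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.arms) < 2:
            raise ValidationError(f"trial {self.trial_id!r}: need >=2 arms, got {len(self.arms)}")
        names = [a.name for a in self.arms]
        if len(set(names)) != len(names):
            raise ValidationError(f"trial {self.trial_id!r}: duplicate arm names")
        if not any(a.is_active for a in self.arms):
            raise ValidationError(f"trial {self.trial_id!r}: no active arm")
        if all(a.is_active for a in self.arms):
            raise ValidationError(f"trial {self.trial_id!r}: no comparator (non-active) arm")

        arm_by_name = {a.name: a for a in self.arms}
        seen: dict[str, str] = {}
        fixed: list[AERecord] = []
        for rec in self.records:
            key = normalize_term(rec.term)
            if key in seen:
                raise ValidationError(
                    f"trial {self.trial_id!r}: duplicate AE term {rec.term!r} "
                    f"(collides with {seen[key]!r} after normalization)"
                )
            seen[key] = rec.term
            for arm_name in rec.counts:
                if arm_name not in arm_by_name:
                    raise ValidationError(
                        f"trial {self.trial_id!r}, term {rec.term!r}: unknown arm {arm_name!r}"
                    )
            counts = {a.name: rec.counts.get(a.name, 0) for a in self.arms}
            for a in self.arms:
                if counts[a.name] > a.n:
                    raise ValidationError(
                        f"trial {self.trial_id!r}, term {rec.term!r}, arm {a.name!r}: "
                        f"count {counts[a.name]} exceeds arm size {a.n}"
                    )
            if sum(counts.values()) == 0:
                raise ValidationError(
                    f"trial {self.trial_id!r}, term {rec.term!r}: zero participants in every arm "
                    "(unobserved terms are not stored)"
                )
            fixed.append(AERecord(rec.term, counts))
        self.records = fixed
        self._index = {normalize_term(r.term): r for r in fixed}

    # -- convenience accessors -------------------------------------------------

    @property
    def terms(self) -> list[str]:
        return [r.term for r in self.records]

    @property
    def n_terms(self) -> int:
        return len(self.records)

    def arm(self, name: str) -> Arm:
        for a in self.arms:
            if a.name == name:
                return a
        raise KeyError(f"trial {self.trial_id!r}: no arm named {name!r}")

    @property
    def active_arms(self) -> list[Arm]:
        return [a for a in self.arms if a.is_active]

    @property
    def comparator_arms(self) -> list[Arm]:
        return [a for a in self.arms if not a.is_active]

    def record(self, term: str) -> AERecord:
        try:
            return self._index[normalize_term(term)]
        except KeyError:
            raise KeyError(f"trial {self.trial_id!r}: no AE term {term!r}") from None

    def has_term(self, term: str) -> bool:
        return normalize_term(term) in self._index

    def subset(self, keep_terms: Iterable[str]) -> "AETable":
        """A copy retaining only the given terms (same arms, same order)."""
        keep = {normalize_term(t) for t in keep_terms}
        recs = [r for r in self.records if normalize_term(r.term) in keep]
        return AETable(self.trial_id, list(self.arms), recs)


# -- I/O ----------------------------------------------------------------------


def _table_to_frame(table: AETable) -> pd.DataFrame:
    rows = []
    for rec in table.records:
        for arm in table.arms:
            rows.append(
                {
                    "trial_id": table.trial_id,
                    "arm": arm.name,
                    "n": arm.n,
                    "is_active": int(arm.is_active),
                    "ae_term": rec.term,
                    "count": rec.counts[arm.name],
                }
            )
    if not table.records:  # arm-declaration rows keep empty tables round-trippable
        for arm in table.arms:
            rows.append(
                {
                    "trial_id": table.trial_id,
                    "arm": arm.name,
                    "n": arm.n,
                    "is_active": int(arm.is_active),
                    "ae_term": "",
                    "count": "",
                }
            )
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def _frame_to_table(df: pd.DataFrame) -> AETable:
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"csv_long is missing columns: {missing}")
    trial_ids = df["trial_id"].astype(str).unique().tolist()
    if len(trial_ids) != 1:
        raise SchemaError(f"expected exactly one trial_id per file, found {trial_ids}")
    trial_id = trial_ids[0]

    arms: dict[str, Arm] = {}
    for (arm_name,), sub in df.groupby(["arm"], sort=False):
        ns = sub["n"].astype(int).unique()
        flags = sub["is_active"].astype(int).unique()
        if len(ns) != 1 or len(flags) != 1:
            raise SchemaError(
                f"trial {trial_id!r}, arm {arm_name!r}: inconsistent n or is_active across rows"
            )
        if flags[0] not in (0, 1):
            raise SchemaError(f"arm {arm_name!r}: is_active must be 0 or 1")
        arms[str(arm_name)] = Arm(str(arm_name), int(ns[0]), bool(flags[0]))

    ae_term = df["ae_term"].fillna("").astype(str)
    data = df[ae_term.str.strip() != ""].copy()
    data["ae_term"] = ae_term[data.index]

    seen_pairs: set[tuple[str, str]] = set()
    counts_by_term: dict[str, dict[str, int]] = {}
    term_display: dict[str, str] = {}
    for _, row in data.iterrows():
        key = normalize_term(row["ae_term"])
        pair = (str(row["arm"]), key)
        if pair in seen_pairs:
            raise ValidationError(
                f"trial {trial_id!r}: duplicate row for arm {row['arm']!r}, "
                f"term {row['ae_term']!r}"
            )
        seen_pairs.add(pair)
        term_display.setdefault(key, str(row["ae_term"]))
        counts_by_term.setdefault(key, {})[str(row["arm"])] = int(row["count"])

    records = [AERecord(term_display[k], v) for k, v in counts_by_term.items()]
    return AETable(trial_id, list(arms.values()), records)


def read_table(path: str | Path, format: str = "csv_long") -> AETable:
    """Read one trial's AE table from ``csv_long`` or ``json``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "csv_long":
        df = pd.read_csv(path, dtype={"trial_id": str, "arm": str, "ae_term": str})
        return _frame_to_table(df)
    if format == "json":
        obj = json.loads(path.read_text())
        arms = [Arm(a["name"], int(a["n"]), bool(a["is_active"])) for a in obj["arms"]]
        records = [AERecord(r["term"], r["counts"]) for r in obj.get("records", [])]
        return AETable(str(obj["trial_id"]), arms, records)
    raise ValueError(f"unknown format {format!r}")


def write_table(table: AETable, path: str | Path, format: str = "csv_long") -> None:
    """Write an AE table; ``read_table`` on the result reproduces it exactly."""
    path = Path(path)
    if format == "csv_long":
        _table_to_frame(table).to_csv(path, index=False)
        return
    if format == "json":
        obj = {
            "trial_id": table.trial_id,
            "arms": [{"name": a.name, "n": a.n, "is_active": a.is_active} for a in table.arms],
            "records": [{"term": r.term, "counts": r.counts} for r in table.records],
        }
        path.write_text(json.dumps(obj, indent=1))
        return
    raise ValueError(f"unknown format {format!r}")
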