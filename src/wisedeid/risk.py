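"""Re-identification risk assessment and the sharing gate.

The dataset risk model is the prosecutor model: assuming an attacker who
knows their target is in the dataset, a record's re-identification
probability is ``1 / |equivalence class|``, where an equivalence class is the
set of records sharing identical (post-transformation) quasi-identifier
values.  The dataset aggregate is the worst case (max over records), with
average risk and the unique-record fraction reported for context.

Risk maps to three categories — by default LOW iff max risk <= 0.10 (so every
class has k >= 10 records), MEDIUM iff <= 0.34 (k >= 3), HIGH otherwise — and
the gate applies the sharing semantics: a trusted party may receive LOW or
MEDIUM risk data; a general audience only LOW.

A single record has no population to partition, so a rule-based granularity
heuristic stands in: HIGH while any direct identifier or full-precision
date/postal survives, MEDIUM when three or more generalized quasi-identifiers
remain, LOW otherwise.

When the gate rejects, :func:`recommend` searches greedily for the ladder
step that most increases the minimum class size and iterates until the gate
would accept or every quasi-identifier is exhausted.
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

from .deid import (GENERALIZE, KEEP, SUPPRESS, ActionKind, DeidAction,
                   LADDER_TOP, SharingContext, generalize)
from .detection import AnnotatedRecord, Label, PatternKind, QuasiKind, detect_value_kind
from .errors import OutOfRange, UnparseableValue
from .formats import FlatRecord

MISSING = "<missing>"  # missing quasi values form their own equivalence value

REIDENTIFICATION_PROHIBITION_NOTICE = (
    "Any attempt to re-identify individuals in this de-identified dataset "
    "is prohibited."
)


class RiskCategory(Enum):
    LOW = "LOW"
    MEDIUM = "MEDIUM"
    HIGH = "HIGH"


class GateDecision(Enum):
    ACCEPT = "ACCEPT"
    REJECT = "REJECT"


@dataclass(frozen=True)
class Thresholds:
    """Category boundaries on max risk; defaults correspond to k>=10 / k>=3."""

    low: float = 0.10
    medium: float = 0.34


@dataclass
class EquivalenceClass:
    key: tuple
    size: int
    record_indices: list[int]


@dataclass
class Amendment:
    path: str
    action: Optional[DeidAction]
    note: str = ""

    def as_dict(self) -> dict:
        action = None
        if self.action is not None:
            action = self.action.kind.value
            if self.action.kind is ActionKind.GENERALIZE:
                action += f"({self.action.level})"
        return {"path": self.path, "action": action, "note": self.note}


@dataclass
class RiskReport:
    per_record_risk: list[float]
    max_risk: float
    avg_risk: float
    unique_fraction: float
    category: RiskCategory
    context: SharingContext
    gate: GateDecision
    recommendations: list[Amendment] = field(default_factory=list)
    quasi_paths: list[str] = field(default_factory=list)
    n_records: int = 0
    notice: str = REIDENTIFICATION_PROHIBITION_NOTICE

    def as_dict(self) -> dict:
        return {
            "n_records": self.n_records,
            "quasi_paths": self.quasi_paths,
            "max_risk": self.max_risk,
            "avg_risk": self.avg_risk,
            "unique_fraction": self.unique_fraction,
            "category": self.category.value,
            "context": self.context.value,
            "gate": self.gate.value,
            "recommendations": [a.as_dict() for a in self.recommendations],
            "notice": self.notice,
        }


# ---------------------------------------------------------------------------
# quasi-identifier extraction
# ---------------------------------------------------------------------------

_INDEX_RE = re.compile(r"\[\d+\]")


def indexless(path: str) -> str:
    return _INDEX_RE.sub("", path)


def quasi_tuple(record: FlatRecord, quasi_paths: Sequence[str]) -> tuple:
    """The record's quasi key: one slot per sorted quasi path; repeated leaves
    under the same index-free path are joined deterministically."""
    by_path: dict[str, list[str]] = defaultdict(list)
    for e in record.entries:
        by_path[indexless(e.path)].append(str(e.value))
    return tuple("|".join(by_path[p]) if p in by_path else MISSING
                 for p in sorted(quasi_paths))


# ---------------------------------------------------------------------------
# equivalence classes and prosecutor risk
# ---------------------------------------------------------------------------

def equivalence_classes(records: Sequence, quasi_paths: Sequence[str] = ()
                        ) -> list[EquivalenceClass]:
    """Partition records by exact quasi-tuple equality.

    ``records`` may be FlatRecords (values extracted at ``quasi_paths``) or
    pre-built tuples/dicts of quasi values.  An empty ``quasi_paths`` with
    FlatRecords, or empty tuples, puts every record in one class.
    """
    keys: list[tuple] = []
    for rec in records:
        if isinstance(rec, FlatRecord):
            keys.append(quasi_tuple(rec, quasi_paths))
        elif isinstance(rec, dict):
            keys.append(tuple(rec.get(p, MISSING) for p in sorted(rec if not quasi_paths
                                                                  else quasi_paths)))
        else:
            keys.append(tuple(rec))
    groups: dict[tuple, list[int]] = defaultdict(list)
    for i, key in enumerate(keys):
        groups[key].append(i)
    return [EquivalenceClass(key=key, size=len(idx), record_indices=idx)
            for key, idx in sorted(groups.items())]


def prosecutor_risk(classes: Sequence[EquivalenceClass]) -> dict:
    """Per-record risks 1/|class| and dataset aggregates."""
    n = sum(c.size for c in classes)
    per_record = [0.0] * n
    for c in classes:
        for i in c.record_indices:
            per_record[i] = 1.0 / c.size
    unique = sum(c.size for c in classes if c.size == 1)
    return {
        "per_record_risk": per_record,
        "max_risk": max(per_record),
        "avg_risk": sum(per_record) / n,
        "unique_fraction": unique / n,
    }


def categorize(max_risk: float, thresholds: Thresholds = Thresholds()) -> RiskCategory:
    if not (0.0 < max_risk <= 1.0):
        raise OutOfRange(f"risk must be in (0, 1], got {max_risk}")
    if max_risk <= thresholds.low:
        return RiskCategory.LOW
    if max_risk <= thresholds.medium:
        return RiskCategory.MEDIUM
    return RiskCategory.HIGH


def gate(category: RiskCategory, context: SharingContext) -> GateDecision:
    """Trusted parties may receive LOW and MEDIUM risk; the public only LOW."""
    if category is RiskCategory.LOW:
        return GateDecision.ACCEPT
    if category is RiskCategory.MEDIUM and context is SharingContext.TRUSTED_PARTY:
        return GateDecision.ACCEPT
    return GateDecision.REJECT


# ---------------------------------------------------------------------------
# single-record mode
# ---------------------------------------------------------------------------

def _full_precision_quasi(value: str, kind: Optional[QuasiKind]) -> bool:
    text = str(value)
    if kind is QuasiKind.POSTAL:
        return len(text) > 3
    if kind is QuasiKind.DATE or kind is None:
        return detect_value_kind(text) is PatternKind.DATE
    return False


def single_record_category(annotated: AnnotatedRecord) -> RiskCategory:
    """Granularity heuristic for one record (no population to partition).

    HIGH while a direct identifier or a full-precision date/postal survives;
    MEDIUM when >= 3 generalized quasi-identifier attributes remain; LOW
    otherwise.
    """
    if annotated.entries_with(Label.DIRECT):
        return RiskCategory.HIGH
    quasi = annotated.entries_with(Label.QUASI)
    for entry, cls in quasi:
        if _full_precision_quasi(entry.value, cls.quasi_kind):
            return RiskCategory.HIGH
    quasi_attrs = {indexless(e.path) for e, _ in quasi}
    if len(quasi_attrs) >= 3:
        return RiskCategory.MEDIUM
    return RiskCategory.LOW


# ---------------------------------------------------------------------------
# reporting and recommendations
# ---------------------------------------------------------------------------

def assess(records: Sequence[FlatRecord], quasi_paths: Sequence[str],
           context: SharingContext, thresholds: Thresholds = Thresholds()
           ) -> RiskReport:
    """Full dataset risk report with the gate decision."""
    classes = equivalence_classes(records, quasi_paths)
    stats = prosecutor_risk(classes)
    category = categorize(stats["max_risk"], thresholds)
    return RiskReport(
        per_record_risk=stats["per_record_risk"],
        max_risk=stats["max_risk"],
        avg_risk=stats["avg_risk"],
        unique_fraction=stats["unique_fraction"],
        category=category,
        context=context,
        gate=gate(category, context),
        quasi_paths=sorted(quasi_paths),
        n_records=len(records),
    )


def _coarsen_column(values: list[str], kind: QuasiKind, level: int) -> list[str]:
    out = []
    for v in values:
        if v == MISSING:
            out.append(v)
            continue
        try:
            out.append(generalize(v, kind, level))
        except UnparseableValue:
            out.append("*")
    return out


def _min_class_size(columns: dict[str, list[str]], n: int) -> int:
    rows = [tuple(columns[p][i] for p in sorted(columns)) for i in range(n)]
    return min(Counter(rows).values())


def recommend(records: Sequence[FlatRecord], quasi_paths: Sequence[str],
              quasi_kinds: dict[str, QuasiKind], context: SharingContext,
              levels: Optional[dict[str, int]] = None,
              thresholds: Thresholds = Thresholds()) -> list[Amendment]:
    """Greedy plan amendments that would let the dataset pass the gate.

    At each step, pick the quasi attribute whose next ladder level most
    increases the minimum class size (ties: fewest distinct values, then
    lexicographic path); once all ladders are exhausted, fall back to
    suppression and finally to suggesting the trusted-party context.
    """
    n = len(records)
    if n == 0:
        return []
    paths = sorted(quasi_paths)
    columns = {p: [quasi_tuple(r, [p])[0] for r in records] for p in paths}
    levels = dict(levels or {p: 0 for p in paths})
    for p in paths:
        levels.setdefault(p, 0)
    amendments: list[Amendment] = []

    def current_gate() -> GateDecision:
        m = _min_class_size(columns, n)
        return gate(categorize(1.0 / m, thresholds), context)

    while current_gate() is GateDecision.REJECT:
        candidates = []
        for p in paths:
            kind = quasi_kinds.get(p, QuasiKind.DATE)
            top = LADDER_TOP.get(kind, 0)
            if levels[p] >= top:
                continue
            next_level = levels[p] + 1
            trial = dict(columns)
            trial[p] = _coarsen_column(columns[p], kind, next_level)
            candidates.append((-_min_class_size(trial, n),
                               len(set(columns[p])), p, next_level, trial[p]))
        if candidates:
            candidates.sort()
            _, _, p, next_level, new_col = candidates[0]
            columns[p] = new_col
            levels[p] = next_level
            amendments.append(Amendment(path=p, action=GENERALIZE(next_level)))
            continue
        # ladders exhausted: suppress the most disclosive attribute next
        remaining = [p for p in paths if any(v != "*" for v in columns[p])]
        if not remaining:
            break
        remaining.sort(key=lambda p: (-len(set(columns[p])), p))
        p = remaining[0]
        columns[p] = ["*"] * n
        amendments.append(Amendment(path=p, action=SUPPRESS))
    if current_gate() is GateDecision.REJECT:
        if context is SharingContext.GENERAL_AUDIENCE:
            m = _min_class_size(columns, n)
            if gate(categorize(1.0 / m, thresholds),
                    SharingContext.TRUSTED_PARTY) is GateDecision.ACCEPT:
                amendments.append(Amendment(
                    path="", action=None,
                    note="no amendment passes the public gate; consider "
                         "sharing with a trusted party instead"))
                return amendments
        return []  # no amendment can pass the gate
    return amendments
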