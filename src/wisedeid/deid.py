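"""Context-dependent de-identification engine.

Four operators are applied per element according to a policy keyed by the
element's classification and the sharing context:

* KEEP — pass through unchanged.
* SUPPRESS — remove the leaf (irreversible in the output).
* GENERALIZE(level) — coarsen along a ladder: dates to year (level 1) then a
  5-year band (level 2); postal codes to a 3-character prefix; ages to 5-year
  bands with everything above 89 pooled into "90+" (the usual aggregation that
  keeps very old patients from being singled out).
* PSEUDONYMIZE — replace with a deterministic keyed token via the vault, so
  the same identifier gets the same token everywhere (including references
  inside a bundle) and an authorized holder of the key can reverse it.

The default policy follows the two sharing contexts: a trusted party keeps
pseudonymous linkage and year-level dates; a general-audience (public) release
suppresses every direct identifier and coarsens further.  Policy strength is
monotone: for every key the public action is at least as strong as the
trusted one.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from .detection import (AnnotatedRecord, Classification, HipaaCategory, Label,
                        QuasiKind, bundle_prefix_map, logical_path)
from .errors import UnparseableValue
from .formats import FlatEntry, FlatRecord, ValueKind
from .vault import PseudonymVault, _TOKEN_RE

logger = logging.getLogger(__name__)


class SharingContext(Enum):
    TRUSTED_PARTY = "TRUSTED_PARTY"
    GENERAL_AUDIENCE = "GENERAL_AUDIENCE"


class ActionKind(Enum):
    KEEP = "KEEP"
    SUPPRESS = "SUPPRESS"
    GENERALIZE = "GENERALIZE"
    PSEUDONYMIZE = "PSEUDONYMIZE"


@dataclass(frozen=True)
class DeidAction:
    kind: ActionKind
    level: int = 0

    def strength(self) -> int:
        """Position in the protection order KEEP < GENERALIZE(1) < ... < PSEUDONYMIZE ≈ SUPPRESS."""
        if self.kind is ActionKind.KEEP:
            return 0
        if self.kind is ActionKind.GENERALIZE:
            return self.level
        return 10  # PSEUDONYMIZE and SUPPRESS both fully mask the value


KEEP = DeidAction(ActionKind.KEEP)
SUPPRESS = DeidAction(ActionKind.SUPPRESS)
PSEUDONYMIZE = DeidAction(ActionKind.PSEUDONYMIZE)


def GENERALIZE(level: int) -> DeidAction:
    if level < 1:
        raise ValueError("generalization level must be >= 1")
    return DeidAction(ActionKind.GENERALIZE, level)


# ---------------------------------------------------------------------------
# generalization ladders
# ---------------------------------------------------------------------------

LADDER_TOP = {QuasiKind.DATE: 2, QuasiKind.POSTAL: 1, QuasiKind.AGE: 1,
              QuasiKind.GENDER: 0, QuasiKind.GEO: 0}

_YEAR_RE = re.compile(r"^\d{4}$")
_BAND_RE = re.compile(r"^(\d{4})-(\d{4})$")
_ISO_RE = re.compile(r"^(\d{4})-\d{2}(-\d{2})?([T ].*)?$")
_HL7_TS_RE = re.compile(r"^(\d{4})\d{4,}")
_DMY_RE = re.compile(r"^\d{2}/\d{2}/(\d{4})$")


def _date_year(text: str) -> Optional[int]:
    for rx in (_ISO_RE, _HL7_TS_RE, _DMY_RE):
        m = rx.match(text)
        if m:
            return int(m.group(1))
    if _YEAR_RE.match(text):
        return int(text)
    return None


def generalize(value, kind: QuasiKind, level: int) -> str:
    """Deterministic, idempotent coarsening of a quasi-identifier value."""
    text = str(value).strip()
    if kind is QuasiKind.DATE:
        band = _BAND_RE.match(text)
        if band:
            return text  # already at the 5-year band level
        year = _date_year(text)
        if year is None:
            raise UnparseableValue(f"not a date: {text!r}")
        if level <= 1:
            return str(year)
        lo = (year // 5) * 5
        return f"{lo}-{lo + 4}"
    if kind is QuasiKind.POSTAL:
        if not text:
            raise UnparseableValue("empty postal code")
        return text[:3]
    if kind is QuasiKind.AGE:
        if text.endswith("+"):
            return text
        band = _BAND_RE.match(text)
        if band:
            return text
        try:
            age = int(float(text))
        except ValueError:
            raise UnparseableValue(f"not an age: {text!r}") from None
        if age > 89:
            return "90+"
        lo = (age // 5) * 5
        return f"{lo}-{lo + 4}"
    raise UnparseableValue(f"no generalization ladder for {kind}")


# ---------------------------------------------------------------------------
# policy
# ---------------------------------------------------------------------------

@dataclass
class DeidPolicy:
    """Mapping (label, sub-key, context) -> action, with per-label defaults.

    Sub-key is the HIPAA category name for DIRECT entries and the quasi kind
    for QUASI entries; ``None`` rows are the label default.
    """

    table: dict = field(default_factory=dict)

    def action_for(self, cls: Classification, context: SharingContext) -> DeidAction:
        if cls.label is Label.DIRECT:
            subkey = cls.hipaa_category.value if cls.hipaa_category else None
        elif cls.label is Label.QUASI:
            subkey = cls.quasi_kind.value if cls.quasi_kind else None
        else:
            subkey = None
        for key in ((cls.label, subkey, context), (cls.label, None, context)):
            if key in self.table:
                return self.table[key]
        return KEEP

    def validate_monotone(self) -> None:
        """Public release must never be weaker than trusted-party sharing."""
        keys = {(label, sub) for (label, sub, _ctx) in self.table}
        for label, sub in keys:
            fake = Classification(
                label=label,
                hipaa_category=HipaaCategory(sub) if label is Label.DIRECT and sub else None,
                quasi_kind=QuasiKind(sub) if label is Label.QUASI and sub else None,
            )
            trusted = self.action_for(fake, SharingContext.TRUSTED_PARTY)
            public = self.action_for(fake, SharingContext.GENERAL_AUDIENCE)
            if public.strength() < trusted.strength():
                raise ValueError(
                    f"policy not monotone for ({label}, {sub}): "
                    f"{public} weaker than {trusted}")


def default_policy() -> DeidPolicy:
    T, G = SharingContext.TRUSTED_PARTY, SharingContext.GENERAL_AUDIENCE
    D, Q, S, O = Label.DIRECT, Label.QUASI, Label.SENSITIVE, Label.OTHER
    table = {
        # direct identifiers: pseudonymize linkable ones for trusted parties,
        # suppress media-like identifiers that carry no linkage utility
        (D, None, T): PSEUDONYMIZE,
        (D, HipaaCategory.FULL_FACE_PHOTO.value, T): SUPPRESS,
        (D, HipaaCategory.BIOMETRIC_IDENTIFIER.value, T): SUPPRESS,
        (D, None, G): SUPPRESS,
        # quasi-identifiers
        (Q, QuasiKind.DATE.value, T): GENERALIZE(1),
        (Q, QuasiKind.DATE.value, G): GENERALIZE(2),
        (Q, QuasiKind.POSTAL.value, T): GENERALIZE(1),
        (Q, QuasiKind.POSTAL.value, G): SUPPRESS,
        (Q, QuasiKind.AGE.value, T): GENERALIZE(1),
        (Q, QuasiKind.AGE.value, G): GENERALIZE(1),
        (Q, QuasiKind.GENDER.value, T): KEEP,
        (Q, QuasiKind.GENDER.value, G): KEEP,
        (Q, QuasiKind.GEO.value, T): KEEP,
        (Q, QuasiKind.GEO.value, G): SUPPRESS,
        (Q, None, T): KEEP,
        (Q, None, G): SUPPRESS,
        # sensitive attributes are flagged, not transformed; policy may override
        (S, None, T): KEEP,
        (S, None, G): KEEP,
        (O, None, T): KEEP,
        (O, None, G): KEEP,
    }
    policy = DeidPolicy(table=table)
    policy.validate_monotone()
    return policy


# ---------------------------------------------------------------------------
# pseudonymization
# ---------------------------------------------------------------------------

_REFERENCE_RE = re.compile(r"^([A-Za-z]+)/(.+)$")


def pseudonymize(value, category: str, vault: PseudonymVault) -> str:
    """Keyed deterministic pseudonym; a value that already is one passes through."""
    text = str(value).strip()
    if _TOKEN_RE.fullmatch(text):
        return text
    ref = _REFERENCE_RE.match(text)
    if ref and _TOKEN_RE.fullmatch(ref.group(2)):
        return text
    return vault.token(category, text)


def reidentify(pseudonym: str, vault: PseudonymVault) -> str:
    """Exact original for a vault-known pseudonym."""
    return vault.original(pseudonym)


# ---------------------------------------------------------------------------
# plan & apply
# ---------------------------------------------------------------------------

@dataclass
class ActionPlan:
    actions: list[DeidAction]            # index-aligned with the flat record
    classifications: list[Classification]
    context: SharingContext

    def overridden(self, overrides: dict[int, DeidAction]) -> "ActionPlan":
        actions = [overrides.get(i, a) for i, a in enumerate(self.actions)]
        return ActionPlan(actions=actions, classifications=self.classifications,
                          context=self.context)


def plan(annotated: AnnotatedRecord, context: SharingContext,
         policy: DeidPolicy) -> ActionPlan:
    """One action per entry; a pure function of (annotations, context, policy)."""
    actions = [policy.action_for(cls, context) for cls in annotated.annotations]
    return ActionPlan(actions=actions, classifications=annotated.annotations,
                      context=context)


def _pseudonym_for_entry(entry: FlatEntry, cls: Classification,
                         vault: PseudonymVault, prefixes: dict[str, str]) -> str:
    """Token for an entry, normalizing ids and references to ``Type/id`` form
    so the same resource identity maps to the same token everywhere."""
    category = cls.hipaa_category.value if cls.hipaa_category else "GEN"
    text = str(entry.value).strip()
    if _TOKEN_RE.fullmatch(text):
        return text
    ref = _REFERENCE_RE.match(text)
    if ref:
        if _TOKEN_RE.fullmatch(ref.group(2)):
            return text
        return f"{ref.group(1)}/" + vault.token(
            HipaaCategory.OTHER_UNIQUE_IDENTIFIER.value, text)
    lpath = logical_path(entry.path, prefixes)
    parts = lpath.split(".")
    if len(parts) == 2 and parts[1] == "id":
        # a resource id: key the token on "Type/id", matching references to it
        return vault.token(HipaaCategory.OTHER_UNIQUE_IDENTIFIER.value,
                           f"{parts[0]}/{text}")
    return pseudonymize(text, category, vault)


def apply(flat: FlatRecord, action_plan: ActionPlan,
          vault: Optional[PseudonymVault] = None) -> FlatRecord:
    """Execute a plan over a flat record, returning the de-identified record.

    With a vault and a trusted-party context, suppressed and generalized
    originals are recorded in the vault's restore section so an authorized
    re-identification can reproduce the original document exactly.
    """
    if len(action_plan.actions) != len(flat.entries):
        raise ValueError("plan is not aligned with the record")
    record_restores = (vault is not None
                       and action_plan.context is SharingContext.TRUSTED_PARTY)
    if record_restores:
        vault.restores.pop(flat.source_id, None)  # idempotent re-runs
        vault.record_order(flat.source_id, [e.path for e in flat.entries])
    prefixes = bundle_prefix_map(flat)
    out: list[FlatEntry] = []
    for entry, action, cls in zip(flat.entries, action_plan.actions,
                                  action_plan.classifications):
        if action.kind is ActionKind.KEEP:
            out.append(entry)
            continue
        if action.kind is ActionKind.SUPPRESS:
            if record_restores:
                vault.record_restore(flat.source_id, entry.path, entry.value,
                                     entry.value_kind.value)
            continue
        if action.kind is ActionKind.GENERALIZE:
            kind = cls.quasi_kind or QuasiKind.DATE
            try:
                new_value = generalize(entry.value, kind, action.level)
            except UnparseableValue:
                logger.warning("cannot generalize %s=%r as %s; suppressing",
                               entry.path, "<redacted>", kind.value)
                if record_restores:
                    vault.record_restore(flat.source_id, entry.path, entry.value,
                                         entry.value_kind.value)
                continue
            if record_restores and new_value != str(entry.value):
                vault.record_restore(flat.source_id, entry.path, entry.value,
                                     entry.value_kind.value)
            kept_kind = (ValueKind.ATTRIBUTE if entry.value_kind is ValueKind.ATTRIBUTE
                         else ValueKind.TEXT)
            out.append(FlatEntry(entry.path, new_value, kept_kind))
            continue
        # PSEUDONYMIZE
        if vault is None:
            raise ValueError("pseudonymization requires a vault")
        token = _pseudonym_for_entry(entry, cls, vault, prefixes)
        kept_kind = (ValueKind.ATTRIBUTE if entry.value_kind is ValueKind.ATTRIBUTE
                     else ValueKind.TEXT)
        out.append(FlatEntry(entry.path, token, kept_kind))
    return FlatRecord(entries=out, format=flat.format, source_id=flat.source_id)
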