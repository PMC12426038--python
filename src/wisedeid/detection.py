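"""Identifier detection: classify flattened elements as direct identifiers,
quasi-identifiers, sensitive attributes, or other.

Classification is driven by a rule registry.  A rule targets a glob over path
segments (bracket indices are ignored when matching, so ``Patient.name.family``
matches ``Patient.name[0].family``), optionally constrained by a named value
pattern, and carries a label, an optional HIPAA Safe Harbor category and a
priority.  The default registry implements the 18-category Safe Harbor list:
direct identifiers (names, record numbers, telecoms, ...) plus the date and
geographic categories, which are treated as quasi-identifiers because years
and 3-digit postal prefixes may be retained under Safe Harbor.

Value patterns double as a safety net: an identifier-looking value sitting at
a path no rule covers is escalated (EMAIL/PHONE/SSN/URL/IP to DIRECT, dates to
QUASI) so identifiers planted in unexpected fields still get protected.
"""

from __future__ import annotations

import fnmatch
import ipaddress
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import yaml

from .errors import UnknownMode
from .formats import FlatRecord, split_path
from .vault import _TOKEN_RE as _VAULT_TOKEN_RE


class Label(Enum):
    DIRECT = "DIRECT"
    QUASI = "QUASI"
    SENSITIVE = "SENSITIVE"
    OTHER = "OTHER"


class HipaaCategory(Enum):
    """The 18 HIPAA Safe Harbor identifier categories."""

    NAME = "NAME"
    GEOGRAPHIC_SUBDIVISION = "GEOGRAPHIC_SUBDIVISION"
    DATE = "DATE"
    PHONE = "PHONE"
    FAX = "FAX"
    EMAIL = "EMAIL"
    SSN = "SSN"
    MEDICAL_RECORD_NUMBER = "MEDICAL_RECORD_NUMBER"
    HEALTH_PLAN_NUMBER = "HEALTH_PLAN_NUMBER"
    ACCOUNT_NUMBER = "ACCOUNT_NUMBER"
    CERTIFICATE_LICENSE_NUMBER = "CERTIFICATE_LICENSE_NUMBER"
    VEHICLE_IDENTIFIER = "VEHICLE_IDENTIFIER"
    DEVICE_IDENTIFIER = "DEVICE_IDENTIFIER"
    URL = "URL"
    IP_ADDRESS = "IP_ADDRESS"
    BIOMETRIC_IDENTIFIER = "BIOMETRIC_IDENTIFIER"
    FULL_FACE_PHOTO = "FULL_FACE_PHOTO"
    OTHER_UNIQUE_IDENTIFIER = "OTHER_UNIQUE_IDENTIFIER"


class PatternKind(Enum):
    EMAIL = "EMAIL"
    URL = "URL"
    IP = "IP"
    SSN_LIKE = "SSN_LIKE"
    PHONE = "PHONE"
    DATE = "DATE"
    ID_TOKEN = "ID_TOKEN"


class Confidence(Enum):
    PATH_RULE = "PATH_RULE"
    VALUE_PATTERN = "VALUE_PATTERN"
    BOTH = "BOTH"


class QuasiKind(Enum):
    """What generalization ladder applies to a quasi-identifier."""

    DATE = "DATE"
    POSTAL = "POSTAL"
    GENDER = "GENDER"
    AGE = "AGE"
    GEO = "GEO"


@dataclass(frozen=True)
class Classification:
    label: Label
    hipaa_category: Optional[HipaaCategory] = None
    rule_id: str = ""
    confidence: Confidence = Confidence.PATH_RULE
    quasi_kind: Optional[QuasiKind] = None


OTHER_CLASSIFICATION = Classification(label=Label.OTHER, rule_id="default-other")


@dataclass(frozen=True)
class DetectionRule:
    rule_id: str
    target: str  # glob over path segments, resource-type anchored; "**" crosses levels
    label: Label
    hipaa_category: Optional[HipaaCategory] = None
    value_pattern: Optional[PatternKind] = None
    priority: int = 50
    quasi_kind: Optional[QuasiKind] = None
    # map from the value of a sibling element (e.g. ContactPoint.system) to a
    # category, used where a lone (path, value) pair cannot disambiguate
    sibling_field: Optional[str] = None
    sibling_category_map: Optional[dict] = None


# ---------------------------------------------------------------------------
# value patterns
# ---------------------------------------------------------------------------

_EMAIL_RE = re.compile(r"^(mailto:)?[\w.+-]+@[\w-]+(\.[\w-]+)+$")
_URL_RE = re.compile(r"^https?://\S+$", re.IGNORECASE)
_SSN_RE = re.compile(r"^\d{3}-\d{2}-\d{4}$")
_PHONE_RE = re.compile(r"^(tel:|fax:)?\+?[\d\s().-]{7,20}$")
_DATE_RES = (
    re.compile(r"^\d{4}-\d{2}-\d{2}([T ][\d:.+Z-]+)?$"),   # ISO date / datetime
    re.compile(r"^\d{4}-\d{2}$"),                           # ISO year-month
    re.compile(r"^\d{2}/\d{2}/\d{4}$"),                     # numeric dd/mm/yyyy
    re.compile(r"^\d{8}(\d{4,6})?([+-]\d{4})?$"),           # HL7 TS: yyyymmdd[hhmm[ss]]
)
_ID_TOKEN_RE = re.compile(r"^[A-Za-z0-9][A-Za-z0-9:/._-]{5,}$")
_YEAR_BAND_RE = re.compile(r"^\d{4}-\d{4}$")  # an already-generalized 5-year band
_IDISH_SEGMENTS = {"id", "identifier", "reference", "fullUrl", "uuid", "root", "extension"}


def _is_ip(text: str) -> bool:
    try:
        ipaddress.ip_address(text)
        return True
    except ValueError:
        return False


def _matching_kinds(text: str) -> set[PatternKind]:
    kinds: set[PatternKind] = set()
    if _EMAIL_RE.match(text):
        kinds.add(PatternKind.EMAIL)
    if _URL_RE.match(text):
        kinds.add(PatternKind.URL)
    if _is_ip(text):
        kinds.add(PatternKind.IP)
    if _SSN_RE.match(text):
        kinds.add(PatternKind.SSN_LIKE)
    date = any(r.match(text) for r in _DATE_RES)
    if date:
        kinds.add(PatternKind.DATE)
    if _PHONE_RE.match(text) and sum(c.isdigit() for c in text) >= 7 and not date \
            and not _SSN_RE.match(text) and not _YEAR_BAND_RE.match(text):
        kinds.add(PatternKind.PHONE)
    return kinds


# fixed tie-break order, most specific first
_KIND_ORDER = [PatternKind.EMAIL, PatternKind.URL, PatternKind.IP,
               PatternKind.SSN_LIKE, PatternKind.PHONE, PatternKind.DATE,
               PatternKind.ID_TOKEN]


def _path_is_idish(path: str) -> bool:
    try:
        segments, attr = split_path(path)
    except Exception:
        return False
    names = {name for name, _ in segments}
    if attr is not None:
        names.add(attr)
    return bool(names & _IDISH_SEGMENTS)


def detect_value_kind(value, path: str = "") -> Optional[PatternKind]:
    """Identify an identifier-shaped scalar value; None for ordinary text.

    ID_TOKEN fires only under an id-ish path (``id``/``identifier``/
    ``reference``/...): alphanumeric tokens are too common elsewhere.
    """
    if not isinstance(value, str) or not value:
        return None
    text = value.strip()
    kinds = _matching_kinds(text)
    if not kinds and _ID_TOKEN_RE.match(text) and any(c.isdigit() for c in text) \
            and _path_is_idish(path):
        return PatternKind.ID_TOKEN
    for kind in _KIND_ORDER:
        if kind in kinds:
            return kind
    return None


# escalation targets for identifier-looking values at uncovered paths
_ESCALATION = {
    PatternKind.EMAIL: (Label.DIRECT, HipaaCategory.EMAIL),
    PatternKind.URL: (Label.DIRECT, HipaaCategory.URL),
    PatternKind.IP: (Label.DIRECT, HipaaCategory.IP_ADDRESS),
    PatternKind.SSN_LIKE: (Label.DIRECT, HipaaCategory.SSN),
    PatternKind.PHONE: (Label.DIRECT, HipaaCategory.PHONE),
    PatternKind.DATE: (Label.QUASI, HipaaCategory.DATE),
}

_PATTERN_CATEGORY = {
    PatternKind.EMAIL: HipaaCategory.EMAIL,
    PatternKind.URL: HipaaCategory.URL,
    PatternKind.IP: HipaaCategory.IP_ADDRESS,
    PatternKind.SSN_LIKE: HipaaCategory.SSN,
    PatternKind.PHONE: HipaaCategory.PHONE,
    PatternKind.DATE: HipaaCategory.DATE,
}


# ---------------------------------------------------------------------------
# path glob matching
# ---------------------------------------------------------------------------

def _pattern_parts(pattern: str) -> tuple[list[str], Optional[str]]:
    attr = None
    if "@" in pattern:
        pattern, attr = pattern.rsplit("@", 1)
    return pattern.split("."), attr


def _match_segments(pat: list[str], seg: list[str]) -> bool:
    if not pat:
        return not seg
    head = pat[0]
    if head == "**":
        # greedy descent across any number of levels (including zero)
        return any(_match_segments(pat[1:], seg[i:]) for i in range(len(seg) + 1))
    if not seg:
        return False
    return fnmatch.fnmatchcase(seg[0], head) and _match_segments(pat[1:], seg[1:])


def path_matches(pattern: str, path: str) -> bool:
    """Glob match over path segments; bracket indices in the path are ignored."""
    try:
        segments, attr = split_path(path)
    except Exception:
        return False
    pat_parts, pat_attr = _pattern_parts(pattern)
    names = [name for name, _ in segments]
    if pat_attr is not None:
        if attr is None or not fnmatch.fnmatchcase(attr, pat_attr):
            return False
    elif attr is not None:
        return False
    return _match_segments(pat_parts, names)


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

@dataclass
class Registry:
    rules: list[DetectionRule] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.rule_id for r in self.rules]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate rule_ids in registry: {dupes}")
        # total priority order; ties broken by rule_id so insertion order is moot
        self.rules.sort(key=lambda r: (-r.priority, r.rule_id))

    def hipaa_categories(self) -> set[HipaaCategory]:
        """Distinct Safe Harbor categories covered by identifier rules.

        Includes categories a rule resolves through a sibling-context map
        (e.g. the telecom rule covers PHONE, FAX, EMAIL and URL).
        """
        cats: set[HipaaCategory] = set()
        for r in self.rules:
            if r.label not in (Label.DIRECT, Label.QUASI):
                continue
            if r.hipaa_category is not None:
                cats.add(r.hipaa_category)
            if r.sibling_category_map:
                cats.update(HipaaCategory(v) for v in r.sibling_category_map.values())
        return cats

    def direct_categories(self) -> set[HipaaCategory]:
        return {r.hipaa_category for r in self.rules
                if r.hipaa_category is not None and r.label is Label.DIRECT}

    def to_yaml(self) -> str:
        rows = []
        for r in self.rules:
            rows.append({
                "rule_id": r.rule_id, "target": r.target, "label": r.label.value,
                "hipaa_category": r.hipaa_category.value if r.hipaa_category else None,
                "value_pattern": r.value_pattern.value if r.value_pattern else None,
                "priority": r.priority,
                "quasi_kind": r.quasi_kind.value if r.quasi_kind else None,
                "sibling_field": r.sibling_field,
                "sibling_category_map": r.sibling_category_map,
            })
        return yaml.safe_dump({"rules": rows}, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "Registry":
        data = yaml.safe_load(text)
        rules = []
        for row in data.get("rules", []):
            rules.append(DetectionRule(
                rule_id=row["rule_id"], target=row["target"],
                label=Label(row["label"]),
                hipaa_category=HipaaCategory(row["hipaa_category"]) if row.get("hipaa_category") else None,
                value_pattern=PatternKind(row["value_pattern"]) if row.get("value_pattern") else None,
                priority=int(row.get("priority", 50)),
                quasi_kind=QuasiKind(row["quasi_kind"]) if row.get("quasi_kind") else None,
                sibling_field=row.get("sibling_field"),
                sibling_category_map=row.get("sibling_category_map"),
            ))
        return cls(rules=rules)


_TELECOM_MAP = {"phone": "PHONE", "fax": "FAX", "email": "EMAIL", "url": "URL",
                "sms": "PHONE", "pager": "PHONE"}


def default_registry(mode: str = "SAFE_HARBOR") -> Registry:
    """The built-in Safe Harbor registry for FHIR R4-shaped JSON and CDA XML."""
    if mode != "SAFE_HARBOR":
        raise UnknownMode(f"unknown registry mode {mode!r}")
    D, Q, S, O = Label.DIRECT, Label.QUASI, Label.SENSITIVE, Label.OTHER
    H = HipaaCategory
    rules = [
        # --- FHIR: names -------------------------------------------------
        DetectionRule("fhir-patient-name", "**.Patient.name.**", D, H.NAME, priority=100),
        DetectionRule("fhir-practitioner-name", "**.Practitioner.name.**", D, H.NAME, priority=100),
        DetectionRule("fhir-contact-name", "**.contact.name.**", D, H.NAME, priority=100),
        # --- FHIR: identifiers & references ------------------------------
        DetectionRule("fhir-ssn-identifier", "**.identifier.value", D, H.SSN,
                      value_pattern=PatternKind.SSN_LIKE, priority=110),
        DetectionRule("fhir-identifier-value", "**.identifier.value", D,
                      H.MEDICAL_RECORD_NUMBER, priority=100),
        DetectionRule("fhir-resource-id", "*.id", D, H.OTHER_UNIQUE_IDENTIFIER, priority=95),
        DetectionRule("fhir-reference", "**.reference", D, H.OTHER_UNIQUE_IDENTIFIER,
                      priority=95),
        DetectionRule("fhir-fullurl", "Bundle.entry.fullUrl", D, H.OTHER_UNIQUE_IDENTIFIER,
                      priority=95),
        # --- FHIR: telecom (system sibling disambiguates phone/fax/email/url)
        DetectionRule("fhir-telecom-value", "**.telecom.value", D, H.PHONE, priority=100,
                      sibling_field="system", sibling_category_map=_TELECOM_MAP),
        # --- FHIR: address ------------------------------------------------
        DetectionRule("fhir-address-line", "**.address.line", D,
                      H.GEOGRAPHIC_SUBDIVISION, priority=100),
        DetectionRule("fhir-address-text", "**.address.text", D,
                      H.GEOGRAPHIC_SUBDIVISION, priority=100),
        DetectionRule("fhir-address-postal", "**.address.postalCode", Q,
                      H.GEOGRAPHIC_SUBDIVISION, priority=100, quasi_kind=QuasiKind.POSTAL),
        DetectionRule("fhir-address-city", "**.address.city", Q,
                      H.GEOGRAPHIC_SUBDIVISION, priority=100, quasi_kind=QuasiKind.GEO),
        DetectionRule("fhir-address-district", "**.address.district", Q,
                      H.GEOGRAPHIC_SUBDIVISION, priority=100, quasi_kind=QuasiKind.GEO),
        # --- FHIR: dates (quasi — Safe Harbor allows year) ----------------
        DetectionRule("fhir-birthdate", "Patient.birthDate", Q, H.DATE, priority=100,
                      quasi_kind=QuasiKind.DATE),
        DetectionRule("fhir-deceased-date", "Patient.deceasedDateTime", Q, H.DATE,
                      priority=100, quasi_kind=QuasiKind.DATE),
        DetectionRule("fhir-encounter-period", "Encounter.period.*", Q, H.DATE,
                      priority=100, quasi_kind=QuasiKind.DATE),
        DetectionRule("fhir-diagnosticreport-dates", "DiagnosticReport.effectiveDateTime",
                      Q, H.DATE, priority=100, quasi_kind=QuasiKind.DATE),
        DetectionRule("fhir-diagnosticreport-issued", "DiagnosticReport.issued", Q,
                      H.DATE, priority=100, quasi_kind=QuasiKind.DATE),
        # --- FHIR: gender (quasi, no Safe Harbor category) -----------------
        DetectionRule("fhir-gender", "Patient.gender", Q, priority=100,
                      quasi_kind=QuasiKind.GENDER),
        # --- FHIR: remaining Safe Harbor categories ------------------------
        DetectionRule("fhir-coverage-subscriber", "Coverage.subscriberId", D,
                      H.HEALTH_PLAN_NUMBER, priority=100),
        DetectionRule("fhir-account-identifier", "Account.identifier.value", D,
                      H.ACCOUNT_NUMBER, priority=105),
        DetectionRule("fhir-qualification-id", "Practitioner.qualification.identifier.value",
                      D, H.CERTIFICATE_LICENSE_NUMBER, priority=105),
        DetectionRule("fhir-device-identifier", "Device.identifier.value", D,
                      H.DEVICE_IDENTIFIER, priority=105),
        DetectionRule("fhir-device-udi", "Device.udiCarrier.deviceIdentifier", D,
                      H.DEVICE_IDENTIFIER, priority=105),
        DetectionRule("fhir-photo", "Patient.photo.**", D, H.FULL_FACE_PHOTO, priority=100),
        # extension hooks: no standard structured R4 element carries these,
        # but planted/exported values at these names must still be caught
        DetectionRule("ext-vehicle-id", "**.vehicleIdentificationNumber", D,
                      H.VEHICLE_IDENTIFIER, priority=100),
        DetectionRule("ext-biometric-id", "**.biometricIdentifier", D,
                      H.BIOMETRIC_IDENTIFIER, priority=100),
        # --- FHIR: sensitive ----------------------------------------------
        DetectionRule("fhir-condition-code", "Condition.code.**", S, priority=90),
        DetectionRule("fhir-procedure-code", "Procedure.code.**", S, priority=90),
        DetectionRule("fhir-observation-code", "Observation.code.**", S, priority=90),
        DetectionRule("fhir-observation-value", "Observation.value*", S, priority=90),
        DetectionRule("fhir-observation-value-cc", "Observation.valueCodeableConcept.**",
                      S, priority=90),
        DetectionRule("fhir-observation-value-qty", "Observation.valueQuantity.**", S,
                      priority=90),
        DetectionRule("fhir-medication-code", "MedicationRequest.medicationCodeableConcept.**",
                      S, priority=90),
        DetectionRule("fhir-immunization-code", "Immunization.vaccineCode.**", S, priority=90),
        # --- CDA ----------------------------------------------------------
        DetectionRule("cda-patient-name", "**.patientRole.patient.name.**", D, H.NAME,
                      priority=100),
        DetectionRule("cda-patient-id", "**.patientRole.id@extension", D,
                      H.MEDICAL_RECORD_NUMBER, priority=100),
        DetectionRule("cda-patient-id-root", "**.patientRole.id@root", D,
                      H.OTHER_UNIQUE_IDENTIFIER, priority=100),
        DetectionRule("cda-doc-id", "ClinicalDocument.id@*", D,
                      H.OTHER_UNIQUE_IDENTIFIER, priority=100),
        DetectionRule("cda-addr-street", "**.patientRole.addr.streetAddressLine", D,
                      H.GEOGRAPHIC_SUBDIVISION, priority=100),
        DetectionRule("cda-addr-postal", "**.patientRole.addr.postalCode", Q,
                      H.GEOGRAPHIC_SUBDIVISION, priority=100, quasi_kind=QuasiKind.POSTAL),
        DetectionRule("cda-addr-city", "**.patientRole.addr.city", Q,
                      H.GEOGRAPHIC_SUBDIVISION, priority=100, quasi_kind=QuasiKind.GEO),
        DetectionRule("cda-telecom", "**.patientRole.telecom@value", D, H.PHONE,
                      priority=100, sibling_category_map=_TELECOM_MAP),
        DetectionRule("cda-birthtime", "**.patient.birthTime@value", Q, H.DATE,
                      priority=100, quasi_kind=QuasiKind.DATE),
        DetectionRule("cda-gender", "**.patient.administrativeGenderCode@code", Q,
                      priority=100, quasi_kind=QuasiKind.GENDER),
        DetectionRule("cda-section-code", "**.section.entry.**.code@*", S, priority=90),
        DetectionRule("cda-section-value", "**.section.entry.**.value@*", S, priority=90),
        # --- structural guards (terminology URIs are not personal URLs) ----
        DetectionRule("guard-coding-system", "**.coding.system", O, priority=80),
        DetectionRule("guard-system", "**.system", O, priority=79),
        DetectionRule("guard-meta", "*.meta.**", O, priority=80),
        DetectionRule("guard-codesystem-attr", "**@codeSystem", O, priority=80),
        DetectionRule("guard-codesystem-name", "**@codeSystemName", O, priority=80),
        DetectionRule("guard-type-code", "ClinicalDocument.code@*", O, priority=80),
        DetectionRule("guard-template-id", "**.templateId@*", O, priority=80),
        DetectionRule("guard-effective-time-doc", "ClinicalDocument.effectiveTime@value",
                      O, priority=80),
        # --- value-pattern escalation on otherwise uncovered paths ---------
        DetectionRule("escalate-email", "**", D, H.EMAIL,
                      value_pattern=PatternKind.EMAIL, priority=10),
        DetectionRule("escalate-url", "**", D, H.URL,
                      value_pattern=PatternKind.URL, priority=9),
        DetectionRule("escalate-ip", "**", D, H.IP_ADDRESS,
                      value_pattern=PatternKind.IP, priority=8),
        DetectionRule("escalate-ssn", "**", D, H.SSN,
                      value_pattern=PatternKind.SSN_LIKE, priority=7),
        DetectionRule("escalate-phone", "**", D, H.PHONE,
                      value_pattern=PatternKind.PHONE, priority=6),
        DetectionRule("escalate-date", "**", Q, H.DATE,
                      value_pattern=PatternKind.DATE, priority=5, quasi_kind=QuasiKind.DATE),
    ]
    return Registry(rules=rules)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _resolve_category(rule: DetectionRule, value, path: str,
                      sibling_value: Optional[str]) -> Optional[HipaaCategory]:
    if rule.sibling_category_map:
        if sibling_value is not None:
            mapped = rule.sibling_category_map.get(str(sibling_value).lower())
            if mapped:
                return HipaaCategory(mapped)
        kind = detect_value_kind(value, path)
        if kind in _PATTERN_CATEGORY:
            return _PATTERN_CATEGORY[kind]
    return rule.hipaa_category


PSEUDONYM_CLASSIFICATION = Classification(label=Label.OTHER, rule_id="pseudonym-token")


def _is_pseudonym(value) -> bool:
    if not isinstance(value, str):
        return False
    text = value.strip()
    if _VAULT_TOKEN_RE.fullmatch(text):
        return True
    m = re.match(r"^[A-Za-z]+/(.+)$", text)
    return bool(m and _VAULT_TOKEN_RE.fullmatch(m.group(1)))


def classify_element(path: str, value, registry: Registry,
                     sibling_value: Optional[str] = None) -> Classification:
    """Classify one (path, value) pair with the highest-priority matching rule.

    Rules are pre-sorted by (priority desc, rule_id); the first one whose path
    glob matches and whose value pattern (if any) fires wins, so classification
    is independent of insertion order.  A vault pseudonym token is OTHER by
    construction: a keyed token reveals nothing without the vault secret.
    """
    if _is_pseudonym(value):
        return PSEUDONYM_CLASSIFICATION
    detected = detect_value_kind(value, path)
    for rule in registry.rules:
        if rule.value_pattern is not None and detected is not rule.value_pattern:
            continue
        if not path_matches(rule.target, path):
            continue
        if rule.target == "**" and rule.value_pattern is not None:
            confidence = Confidence.VALUE_PATTERN
        elif detected is not None:
            confidence = Confidence.BOTH
        else:
            confidence = Confidence.PATH_RULE
        category = _resolve_category(rule, value, path, sibling_value)
        quasi_kind = rule.quasi_kind
        if quasi_kind is None and rule.label is Label.QUASI and detected is PatternKind.DATE:
            quasi_kind = QuasiKind.DATE
        return Classification(label=rule.label, hipaa_category=category,
                              rule_id=rule.rule_id, confidence=confidence,
                              quasi_kind=quasi_kind)
    return OTHER_CLASSIFICATION


@dataclass
class AnnotatedRecord:
    flat: FlatRecord
    annotations: list[Classification]

    def __post_init__(self) -> None:
        if len(self.annotations) != len(self.flat.entries):
            raise ValueError("annotations and entries must be index-aligned")

    def counts(self) -> dict[str, int]:
        out = {label.value: 0 for label in Label}
        for ann in self.annotations:
            out[ann.label.value] += 1
        return out

    def entries_with(self, label: Label):
        return [(e, a) for e, a in zip(self.flat.entries, self.annotations)
                if a.label is label]


def _sibling_lookup(flat: FlatRecord) -> dict[str, str]:
    """Map each telecom ``value`` path to its sibling ``system``/``use`` value."""
    by_path = {e.path: e.value for e in flat.entries}
    out: dict[str, str] = {}
    for e in flat.entries:
        if e.path.endswith(".value"):
            sib = e.path[: -len(".value")] + ".system"
            if sib in by_path:
                out[e.path] = str(by_path[sib])
    return out


_BUNDLE_RESOURCE_RE = re.compile(r"^(Bundle\.entry\[\d+\]\.resource)\.resourceType$")


def bundle_prefix_map(flat: FlatRecord) -> dict[str, str]:
    """Map ``Bundle.entry[i].resource`` path prefixes to their resource types."""
    out: dict[str, str] = {}
    for e in flat.entries:
        m = _BUNDLE_RESOURCE_RE.match(e.path)
        if m and isinstance(e.value, str):
            out[m.group(1)] = e.value
    return out


def logical_path(path: str, prefix_map: dict[str, str]) -> str:
    """Rewrite a bundle-entry path so it is anchored at its resource type.

    ``Bundle.entry[0].resource.name[0].family`` classifies as
    ``Patient.name[0].family`` when entry 0 holds a Patient; standalone
    resource paths pass through unchanged.
    """
    for prefix, rtype in prefix_map.items():
        if path.startswith(prefix + ".") or path.startswith(prefix + "@"):
            return rtype + path[len(prefix):]
    return path


def scan(flat: FlatRecord, registry: Registry) -> AnnotatedRecord:
    """Annotate every entry of a flat record (pure, deterministic).

    Bundle-entry paths are classified against their resource-type-anchored
    logical path, so resource-anchored rules apply inside bundles too.
    """
    siblings = _sibling_lookup(flat)
    prefixes = bundle_prefix_map(flat)
    annotations = [
        classify_element(logical_path(e.path, prefixes), e.value, registry,
                         sibling_value=siblings.get(e.path))
        for e in flat.entries
    ]
    return AnnotatedRecord(flat=flat, annotations=annotations)
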