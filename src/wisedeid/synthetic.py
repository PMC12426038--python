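"""Seeded synthetic EHR fixtures with a ground-truth manifest.

Generates small Synthea-like FHIR bundles and minimal CDA documents whose
planted direct identifiers, quasi-identifiers and sensitive attributes are
recorded in a manifest, so detection recall, scrub completeness and risk
calculations can be checked against known truth without any downloads.
Values are plausible but fake; structural fidelity matters more than clinical
realism.

The ``duplication_factor`` d controls equivalence-class structure: the cohort
draws ceil(n/d) distinct quasi tuples (birth date, postal code, gender) and
assigns them to patients as evenly as possible, so the minimum class size —
hence the prosecutor max risk 1/min-size — is known analytically
(:func:`expected_min_class_size`).
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass, field, asdict
from typing import Optional

from lxml import etree

from .detection import HipaaCategory, Label
from .formats import CDA_NS, EhrDocument, FormatKind

_GIVEN = ["Alma", "Bruno", "Clara", "Daniel", "Eva", "Felix", "Greta", "Hugo",
          "Ida", "Jonas", "Katrin", "Lukas", "Mari", "Nils", "Olga", "Paul",
          "Rita", "Sven", "Tiina", "Urmas"]
_FAMILY = ["Aru", "Berg", "Cruz", "Dorn", "Eder", "Falk", "Gruber", "Haas",
           "Ilves", "Jung", "Kask", "Lehm", "Mets", "Nurm", "Oja", "Palm",
           "Rebane", "Saar", "Tamm", "Vaher"]
_CITIES = ["Tallinn", "Tartu", "Narva", "Parnu", "Viljandi", "Rakvere",
           "Kuressaare", "Voru", "Haapsalu", "Paide", "Keila", "Valga"]
_CONDITIONS = [("44054006", "Diabetes mellitus type 2"),
               ("38341003", "Hypertensive disorder"),
               ("195967001", "Asthma"),
               ("13645005", "Chronic obstructive lung disease"),
               ("35489007", "Depressive disorder")]
_OBSERVATIONS = [("8480-6", "Systolic blood pressure", 90, 180, "mm[Hg]"),
                 ("2339-0", "Glucose", 60, 200, "mg/dL"),
                 ("718-7", "Hemoglobin", 10, 18, "g/dL")]
_VACCINES = [("08", "Hep B, adolescent or pediatric"),
             ("140", "Influenza, seasonal, injectable"),
             ("213", "SARS-COV-2 vaccine")]


@dataclass(frozen=True)
class ManifestRow:
    path: str
    value: str
    label: Label
    hipaa_category: Optional[HipaaCategory] = None

    def rebased(self, prefix_from: str, prefix_to: str) -> "ManifestRow":
        if self.path.startswith(prefix_from):
            return ManifestRow(prefix_to + self.path[len(prefix_from):],
                               self.value, self.label, self.hipaa_category)
        return self


@dataclass
class TruthManifest:
    rows: list[ManifestRow] = field(default_factory=list)

    def paths(self, label: Label) -> set[str]:
        return {r.path for r in self.rows if r.label is label}

    def direct_count(self, path_prefix: str = "") -> int:
        return sum(1 for r in self.rows
                   if r.label is Label.DIRECT and r.path.startswith(path_prefix))

    def to_json(self) -> str:
        return json.dumps([{**asdict(r),
                            "label": r.label.value,
                            "hipaa_category": r.hipaa_category.value
                            if r.hipaa_category else None}
                           for r in self.rows], indent=2)


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for a synthetic cohort; same spec + seed => same corpus."""

    n_patients: int = 25
    seed: int = 0
    birth_year_range: tuple[int, int] = (1930, 2005)
    postal_pool: int = 12
    gender_frequencies: tuple[tuple[str, float], ...] = (("female", 0.5), ("male", 0.5))
    n_conditions: int = 1
    n_observations: int = 1
    n_immunizations: int = 1
    duplication_factor: int = 1


def n_quasi_tuples(spec: CohortSpec) -> int:
    return max(1, math.ceil(spec.n_patients / max(1, spec.duplication_factor)))


def expected_min_class_size(spec: CohortSpec) -> int:
    """Minimum equivalence-class size forced by the round-robin tuple assignment."""
    return spec.n_patients // n_quasi_tuples(spec)


def _rng(spec: CohortSpec, stream: str) -> random.Random:
    return random.Random(f"{spec.seed}:{stream}")


def _quasi_tuples(spec: CohortSpec) -> list[tuple[str, str, str]]:
    """ceil(n/d) distinct (birthDate, postalCode, gender) tuples."""
    rng = _rng(spec, "quasi")
    q = n_quasi_tuples(spec)
    y0, y1 = spec.birth_year_range
    dates: set[str] = set()
    while len(dates) < q:
        year = rng.randint(y0, y1)
        dates.add(f"{year:04d}-{rng.randint(1, 12):02d}-{rng.randint(1, 28):02d}")
    postals = [f"{10000 + 137 * i}" for i in range(spec.postal_pool)]
    genders = [g for g, _ in spec.gender_frequencies]
    weights = [w for _, w in spec.gender_frequencies]
    out = []
    for date in sorted(dates):
        out.append((date, rng.choice(postals), rng.choices(genders, weights)[0]))
    return out


def _city_for(postal: str) -> str:
    return _CITIES[int(postal) % len(_CITIES)]


# ---------------------------------------------------------------------------
# FHIR generators
# ---------------------------------------------------------------------------

def generate_patient(spec: CohortSpec, index: int) -> tuple[dict, list[ManifestRow]]:
    """One FHIR Patient with six planted direct identifiers plus quasi plants."""
    rng = _rng(spec, f"patient:{index}")
    tuples = _quasi_tuples(spec)
    birth_date, postal, gender = tuples[index % len(tuples)]
    pid = f"p{index:04d}"
    given = rng.choice(_GIVEN)
    family = rng.choice(_FAMILY)
    mrn = f"MRN{rng.randint(10 ** 6, 10 ** 7 - 1)}"
    phone = f"+372-5{rng.randint(100, 999)}-{rng.randint(1000, 9999)}"
    email = f"{given.lower()}.{family.lower()}{index}@example.org"
    city = _city_for(postal)
    patient = {
        "resourceType": "Patient",
        "id": pid,
        "identifier": [{"system": "urn:oid:1.2.3.4", "value": mrn}],
        "name": [{"family": family, "given": [given]}],
        "telecom": [{"system": "phone", "value": phone},
                    {"system": "email", "value": email}],
        "gender": gender,
        "birthDate": birth_date,
        "address": [{"city": city, "postalCode": postal}],
    }
    D, Q = Label.DIRECT, Label.QUASI
    H = HipaaCategory
    rows = [
        ManifestRow("Patient.id", pid, D, H.OTHER_UNIQUE_IDENTIFIER),
        ManifestRow("Patient.identifier[0].value", mrn, D, H.MEDICAL_RECORD_NUMBER),
        ManifestRow("Patient.name[0].family", family, D, H.NAME),
        ManifestRow("Patient.name[0].given[0]", given, D, H.NAME),
        ManifestRow("Patient.telecom[0].value", phone, D, H.PHONE),
        ManifestRow("Patient.telecom[1].value", email, D, H.EMAIL),
        ManifestRow("Patient.birthDate", birth_date, Q, H.DATE),
        ManifestRow("Patient.address[0].postalCode", postal, Q, H.GEOGRAPHIC_SUBDIVISION),
        ManifestRow("Patient.address[0].city", city, Q, H.GEOGRAPHIC_SUBDIVISION),
        ManifestRow("Patient.gender", gender, Q, None),
    ]
    return patient, rows


def _attached_resources(spec: CohortSpec, index: int, pid: str
                        ) -> list[tuple[dict, list[ManifestRow]]]:
    rng = _rng(spec, f"resources:{index}")
    out: list[tuple[dict, list[ManifestRow]]] = []
    D, S, Q = Label.DIRECT, Label.SENSITIVE, Label.QUASI
    H = HipaaCategory
    for c in range(spec.n_conditions):
        code, display = rng.choice(_CONDITIONS)
        rid = f"c{index:04d}-{c}"
        out.append(({
            "resourceType": "Condition",
            "id": rid,
            "code": {"coding": [{"system": "http://snomed.info/sct",
                                 "code": code, "display": display}]},
            "subject": {"reference": f"Patient/{pid}"},
        }, [
            ManifestRow("Condition.id", rid, D, H.OTHER_UNIQUE_IDENTIFIER),
            ManifestRow("Condition.subject.reference", f"Patient/{pid}", D,
                        H.OTHER_UNIQUE_IDENTIFIER),
            ManifestRow("Condition.code.coding[0].code", code, S),
            ManifestRow("Condition.code.coding[0].display", display, S),
        ]))
    for o in range(spec.n_observations):
        code, display, lo, hi, unit = rng.choice(_OBSERVATIONS)
        rid = f"o{index:04d}-{o}"
        value = rng.randint(lo, hi)
        out.append(({
            "resourceType": "Observation",
            "id": rid,
            "status": "final",
            "code": {"coding": [{"system": "http://loinc.org",
                                 "code": code, "display": display}]},
            "subject": {"reference": f"Patient/{pid}"},
            "valueQuantity": {"value": value, "unit": unit},
        }, [
            ManifestRow("Observation.id", rid, D, H.OTHER_UNIQUE_IDENTIFIER),
            ManifestRow("Observation.subject.reference", f"Patient/{pid}", D,
                        H.OTHER_UNIQUE_IDENTIFIER),
            ManifestRow("Observation.code.coding[0].code", code, S),
            ManifestRow("Observation.code.coding[0].display", display, S),
        ]))
    for m in range(spec.n_immunizations):
        code, display = rng.choice(_VACCINES)
        rid = f"i{index:04d}-{m}"
        when = f"{rng.randint(2015, 2024)}-{rng.randint(1, 12):02d}-{rng.randint(1, 28):02d}"
        out.append(({
            "resourceType": "Immunization",
            "id": rid,
            "status": "completed",
            "vaccineCode": {"coding": [{"system": "http://hl7.org/fhir/sid/cvx",
                                        "code": code, "display": display}]},
            "patient": {"reference": f"Patient/{pid}"},
            "occurrenceDateTime": when,
        }, [
            ManifestRow("Immunization.id", rid, D, H.OTHER_UNIQUE_IDENTIFIER),
            ManifestRow("Immunization.patient.reference", f"Patient/{pid}", D,
                        H.OTHER_UNIQUE_IDENTIFIER),
            ManifestRow("Immunization.vaccineCode.coding[0].code", code, S),
            ManifestRow("Immunization.vaccineCode.coding[0].display", display, S),
            # a date planted off the rule-covered paths: caught by pattern escalation
            ManifestRow("Immunization.occurrenceDateTime", when, Q, H.DATE),
        ]))
    return out


def generate_bundle(spec: CohortSpec) -> tuple[EhrDocument, TruthManifest]:
    """A FHIR Bundle of n patients with attached clinical resources."""
    entries = []
    manifest = TruthManifest()
    entry_index = 0
    for i in range(spec.n_patients):
        patient, rows = generate_patient(spec, i)
        prefix = f"Bundle.entry[{entry_index}].resource"
        manifest.rows += [r.rebased(patient["resourceType"], prefix) for r in rows]
        entries.append({"resource": patient})
        entry_index += 1
        for res, rows in _attached_resources(spec, i, patient["id"]):
            prefix = f"Bundle.entry[{entry_index}].resource"
            manifest.rows += [r.rebased(res["resourceType"], prefix) for r in rows]
            entries.append({"resource": res})
            entry_index += 1
    bundle = {"resourceType": "Bundle", "type": "collection", "entry": entries}
    doc = EhrDocument(format=FormatKind.FHIR_JSON_BUNDLE, root=bundle,
                      source_id=f"bundle-seed{spec.seed}")
    return doc, manifest


# ---------------------------------------------------------------------------
# CDA generator
# ---------------------------------------------------------------------------

def generate_cda(spec: CohortSpec, index: int) -> tuple[EhrDocument, TruthManifest]:
    """A minimal ClinicalDocument: recordTarget demographics + one coded section."""
    rng = _rng(spec, f"cda:{index}")
    tuples = _quasi_tuples(spec)
    birth_date, postal, gender = tuples[index % len(tuples)]
    birth_ts = birth_date.replace("-", "")
    given = rng.choice(_GIVEN)
    family = rng.choice(_FAMILY)
    mrn = f"MRN{rng.randint(10 ** 6, 10 ** 7 - 1)}"
    phone = f"tel:+372-5{rng.randint(100, 999)}-{rng.randint(1000, 9999)}"
    doc_id = f"2.16.840.1.113883.19.5.{spec.seed}.{index}"
    city = _city_for(postal)
    gender_code = {"female": "F", "male": "M"}.get(gender, "UN")
    code, display = rng.choice(_CONDITIONS)

    E = lambda parent, name: etree.SubElement(parent, f"{{{CDA_NS}}}{name}")
    root = etree.Element(f"{{{CDA_NS}}}ClinicalDocument", nsmap={None: CDA_NS})
    el = E(root, "id"); el.set("root", doc_id)
    el = E(root, "code"); el.set("code", "34133-9"); el.set("displayName", "Summary of episode note")
    title = E(root, "title"); title.text = "Patient summary"
    el = E(root, "effectiveTime"); el.set("value", "20240101")
    rt = E(root, "recordTarget")
    role = E(rt, "patientRole")
    el = E(role, "id"); el.set("root", "1.2.3.4"); el.set("extension", mrn)
    addr = E(role, "addr")
    E(addr, "city").text = city
    E(addr, "postalCode").text = postal
    el = E(role, "telecom"); el.set("value", phone)
    pat = E(role, "patient")
    name = E(pat, "name")
    E(name, "given").text = given
    E(name, "family").text = family
    el = E(pat, "administrativeGenderCode"); el.set("code", gender_code)
    el = E(pat, "birthTime"); el.set("value", birth_ts)
    comp = E(root, "component")
    body = E(comp, "structuredBody")
    comp2 = E(body, "component")
    section = E(comp2, "section")
    el = E(section, "code"); el.set("code", "11450-4"); el.set("displayName", "Problem list")
    E(section, "title").text = "Problems"
    entry = E(section, "entry")
    obs = E(entry, "observation")
    el = E(obs, "code"); el.set("code", code); el.set("displayName", display)

    D, Q, S = Label.DIRECT, Label.QUASI, Label.SENSITIVE
    H = HipaaCategory
    base = "ClinicalDocument.recordTarget.patientRole"
    manifest = TruthManifest(rows=[
        ManifestRow("ClinicalDocument.id@root", doc_id, D, H.OTHER_UNIQUE_IDENTIFIER),
        ManifestRow(f"{base}.id@extension", mrn, D, H.MEDICAL_RECORD_NUMBER),
        ManifestRow(f"{base}.id@root", "1.2.3.4", D, H.OTHER_UNIQUE_IDENTIFIER),
        ManifestRow(f"{base}.telecom@value", phone, D, H.PHONE),
        ManifestRow(f"{base}.patient.name.given", given, D, H.NAME),
        ManifestRow(f"{base}.patient.name.family", family, D, H.NAME),
        ManifestRow(f"{base}.addr.postalCode", postal, Q, H.GEOGRAPHIC_SUBDIVISION),
        ManifestRow(f"{base}.addr.city", city, Q, H.GEOGRAPHIC_SUBDIVISION),
        ManifestRow(f"{base}.patient.birthTime@value", birth_ts, Q, H.DATE),
        ManifestRow(f"{base}.patient.administrativeGenderCode@code", gender_code, Q, None),
        ManifestRow("ClinicalDocument.component.structuredBody.component.section"
                    ".entry.observation.code@code", code, S),
        ManifestRow("ClinicalDocument.component.structuredBody.component.section"
                    ".entry.observation.code@displayName", display, S),
    ])
    doc = EhrDocument(format=FormatKind.CDA_XML, root=root,
                      source_id=f"cda-seed{spec.seed}-{index}")
    return doc, manifest
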