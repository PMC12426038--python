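# Methods

## Document model and flattening

Both supported formats are reduced to a single flat view: an ordered list of
`(path, value, value_kind)` triples in depth-first document order. Paths are
dot-separated element names with zero-based bracket indices for repeated
siblings (`Patient.name[0].given[1]`) and a trailing `@name` segment for XML
attributes (`...patientRole.id@extension`). This syntax is FHIRPath-like,
unambiguous and trivially parseable, which keeps detection rules auditable.

Flattening is lossless with respect to reconstruction:
`reconstruct(flatten(parse(x)))` equals `parse(x)` under canonical
serialization (sorted-key compact JSON; exclusive-C14N XML). Suppression
deletes entries; on reconstruction, array index gaps are compacted (FHIR
arrays must stay dense) and containers whose leaves were all removed simply
never reappear. For CDA, the default `urn:hl7-org:v3` namespace is stripped
from paths and restored on reconstruction; ignorable whitespace is dropped at
parse time so round trips compare structurally. Encoding is fixed to UTF-8.

Known representational limits (irrelevant to well-formed FHIR/CDA but worth
stating): empty containers (`{}`/`[]`) and nested JSON arrays have no flat
representation; XML mixed content is concatenated into one text leaf per
element, since narrative free text is out of detection scope anyway.

## Identifier detection

Classification is rule-driven. A rule targets a glob over path segments
(indices ignored, `**` crosses levels, `@attr` for attributes), optionally
constrained by a named value pattern, and carries a label (DIRECT / QUASI /
SENSITIVE / OTHER), an optional HIPAA Safe Harbor category, and a priority.
Priorities are totally ordered (ties broken lexicographically by rule id), so
classification does not depend on rule insertion order. The registry is
serializable to YAML for site-specific editing.

The default registry covers all **18 Safe Harbor categories**. Sixteen are
carried by DIRECT rules (names, record numbers, telecoms, street addresses,
health-plan/account/certificate/device identifiers, URLs, IPs, SSNs,
biometrics, photos, resource ids and references, ...). The DATE and
GEOGRAPHIC categories are carried by QUASI rules: Safe Harbor itself permits
retaining the year of a date and a 3-digit ZIP prefix, i.e. these categories
are removed by *generalization* rather than deletion, and treating them as
quasi-identifiers is what makes the equivalence-class risk model meaningful.

Two mechanisms extend pure path matching:

- **Sibling context.** A FHIR `ContactPoint.value` cannot be typed from the
  (path, value) pair alone; `scan` resolves the sibling `system` element to
  distinguish phone / fax / email / URL telecoms, with value-pattern fallback
  when no sibling is available (e.g. CDA `telecom@value` schemes).
- **Value-pattern escalation.** An identifier-shaped value at a path no rule
  covers is escalated conservatively: EMAIL/PHONE/SSN/URL/IP to DIRECT, dates
  to QUASI. Structural guard rules (terminology `system` URIs, `meta`,
  `codeSystem` attributes) sit at higher priority so vocabulary URLs are not
  mistaken for personal ones. ID-like tokens escalate only under id-ish path
  segments (`id`, `identifier`, `reference`, ...), because bare alphanumeric
  strings are too common elsewhere.

Vault pseudonym tokens (`PSN-<CAT>-<16 hex>`) are classified OTHER by
construction: a keyed one-way token reveals nothing without the vault secret.
This is what makes "re-scan the output and find zero direct identifiers" a
meaningful completeness check for trusted-party shares as well.

Bundle entries are classified against a *logical path* in which
`Bundle.entry[i].resource` is replaced by the entry's resource type, so
resource-anchored rules apply identically to standalone resources and bundle
members.

Free-text (narrative) detection is out of scope by design; the generator
therefore plants no identifiers in narrative text.

## De-identification operators and policy

Four operators: KEEP, SUPPRESS, GENERALIZE(level), PSEUDONYMIZE, with the
protection order KEEP < GENERALIZE(1) < GENERALIZE(2) < … < PSEUDONYMIZE ≈
SUPPRESS. Generalization ladders:

| kind   | level 1                   | level 2            | notes |
|--------|---------------------------|--------------------|-------|
| DATE   | year (`"1984"`)           | 5-year band `"1980-1984"` (floor(y/5)·5) | ISO dates/datetimes, HL7 `yyyymmdd…` timestamps, `dd/mm/yyyy` |
| POSTAL | first 3 characters        | —                  | next step is suppression |
| AGE    | 5-year band, `"90+"` above 89 | —              | the over-89 pool prevents singling out the very old |

Generalization is deterministic and idempotent at each level (a year or a
band is a fixed point). A value that does not parse as its kind degrades to
suppression with a logged warning rather than leaking through.

The default policy by sharing context:

| classification        | trusted party         | general audience |
|-----------------------|-----------------------|------------------|
| DIRECT (linkable)     | PSEUDONYMIZE          | SUPPRESS |
| DIRECT photo/biometric| SUPPRESS              | SUPPRESS |
| QUASI date            | GENERALIZE(1) = year  | GENERALIZE(2) = 5-year band |
| QUASI postal          | GENERALIZE(1) = 3 chars | SUPPRESS |
| QUASI gender          | KEEP                  | KEEP |
| QUASI city/district   | KEEP                  | SUPPRESS |
| SENSITIVE             | KEEP (flagged)        | KEEP (flagged) |
| OTHER                 | KEEP                  | KEEP |

`DeidPolicy.validate_monotone` enforces that the public action is never
weaker than the trusted one for any key. Sensitive attributes (diagnoses,
procedures, medications) are flagged but not transformed by default — they
are the data utility being shared; a site policy may override this.
Linkable direct identifiers are pseudonymized rather than suppressed for
trusted parties to preserve longitudinal linkage; media-like identifiers
(photos, biometrics) carry no linkage utility and are always suppressed.

## Pseudonymization and the vault

A pseudonym is `PSN-<category>-<hex16>` where the 16 hex digits are the
truncated HMAC-SHA256 of `(category, normalized original)` under a key
derived from the user-held secret. Determinism gives referential
consistency: resource ids are normalized to `Type/id` before hashing, so
`Patient.id = "123"` and `subject.reference = "Patient/123"` produce the same
token, and references keep their `Type/` prefix and so remain structurally
valid. Pseudonymizing an existing token is the identity, which makes
re-applying a plan to already de-identified output a no-op.

A keyed hash is one-way, so reversibility requires the vault: a bidirectional
token↔original store persisted under authenticated encryption built from the
standard library (HKDF-style derived encrypt/MAC keys, deterministic
SIV-style nonce = HMAC of the plaintext, SHA-256 counter keystream,
encrypt-then-MAC HMAC-SHA256 tag). Opening with a wrong secret fails the tag
check. Deterministic encryption keeps entire runs byte-reproducible.

For trusted-party runs the vault additionally records, per document, the
originals of suppressed and generalized leaves and the original leaf order
(paths only — structure, not values). Generalization and suppression are
many-to-one, so pseudonym reversal alone cannot reproduce the source
document; with the restore section, authorized re-identification is an exact
inverse: the restored document equals the original canonically. Public
(general-audience) outputs are anonymized, never vaulted, and the
re-identification pipeline refuses them. Identifiable data never persists
anywhere except inside this encrypted store, and run reports never contain
original values.

## Risk model

The dataset model is the **prosecutor model** of statistical disclosure
control: the attacker knows the target is in the dataset, so a record's
re-identification probability is `1/|equivalence class|`, where classes
partition records by exact equality of their post-transformation
quasi-identifier tuples (sorted attribute order; missing values are their own
equivalence value — wildcarding them would understate risk). This model was
chosen because it is the standard worst-case measure, exactly computable, and
verifiable against a brute-force group-and-count oracle. The dataset
aggregate is the worst case (`max_risk`), because the gate must protect every
record; average risk and the unique-record fraction are reported for context.

Category thresholds are conventional k-anonymity heuristics, exposed in
configuration: LOW iff `max_risk ≤ 0.10` (every class k ≥ 10), MEDIUM iff
`≤ 0.34` (k ≥ 3), HIGH otherwise. The sharing gate is exact: trusted parties
may receive LOW or MEDIUM; a general audience only LOW.

A **single record** has no population to partition, so a documented
rule-based heuristic stands in: HIGH while any direct identifier or
full-precision date/postal survives; MEDIUM when three or more generalized
quasi-identifier attributes remain; LOW otherwise. The pipeline reports a
nominal risk value inside the category band (1.0 / 0.2 / 0.05) since the
heuristic has no statistical magnitude of its own.

When the gate rejects, `recommend` searches greedily: at each step it takes
the quasi attribute whose next ladder level most increases the minimum class
size (ties: fewest distinct values, then lexicographic path), recomputes, and
stops at ACCEPT or ladder exhaustion, falling back to suppression and finally
to suggesting the trusted-party context. Coarsening any column merges classes
and never splits them, so each step is monotone non-increasing in `max_risk`
and the loop terminates. With `--auto-strengthen` the pipeline applies these
amendments and re-runs the plan from the original input until the gate
accepts or no amendment remains.

Batch runs pool all patient-level records (every Patient resource across all
inputs; each CDA document counts as one patient record) into a single joint
risk computation — risk is a property of the released dataset, not of single
files. Quasi-identifier selection is automatic from detection (`--quasi auto`)
or user-specified paths. Out of scope: journalist/marketer attacker models,
population-sampling estimators, l-diversity/t-closeness.

## Synthetic cohorts

The generator emulates the structure of Synthea-style synthetic exports
offline and seeded: FHIR bundles with Patients (name, MRN-style identifier,
phone and email telecoms, address with city and postal code, birth date,
gender — six direct-identifier plants per Patient plus quasi plants) and
attached Condition/Observation/Immunization resources referencing their
patient, and minimal CDA documents (recordTarget demographics plus one coded
problem section). Every plant is recorded in a truth manifest with its
expected label, so detector recall on the manifest is 100% by construction —
the generator only plants at rule-covered paths or pattern-detectable values
(the immunization date is deliberately planted at a path no rule covers, to
exercise escalation).

Defaults describe a small, plausible cohort: birth years 1930–2005, a
12-postal-code pool, balanced gender, one condition/observation/immunization
per patient. The `duplication_factor` d controls the equivalence-class
structure: the cohort draws `q = ceil(n/d)` distinct quasi tuples (with
distinct birth dates, so raw tuples never collide accidentally) and assigns
them round-robin, forcing the minimum class size to `n // q` — hence the
pipeline's `max_risk` is analytically `1/(n // q)` and is asserted against
that value, not against a measured baseline.

What the generator does **not** emulate — and therefore what passing tests do
not show about real data: clinical realism and longitudinal disease
histories, free-text narrative containing identifiers, profile/terminology
validity, typos and non-canonical date layouts beyond the supported ones, and
identifier distributions of any real population. The detection recall of
100% is a property of the constructed corpus; on real exports, recall depends
on the registry matching the site's actual paths, which is why the registry
is an editable configuration file.

## Determinism and numerical choices

Everything is deterministic by construction: fixture generation derives a
`random.Random` stream per (seed, purpose); pseudonyms, vault encryption and
canonical serialization are functions of (input, secret); plans are pure
functions of (annotations, context, policy); reports carry no timestamps. Two
runs with identical inputs, configuration and key material are byte-identical
— verified end-to-end in the test suite and the acceptance script.

Problem sizes used by the default verification runs: 100 fixtures per format
for round trips, 50 three-patient bundles per context for scrub completeness,
20 random tables up to n = 1000 with up to 5 quasi attributes for the risk
oracle, and 20 tables for monotonicity — sizes at which the brute-force
oracles are exact and the whole suite stays fast.
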