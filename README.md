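# wisedeid

De-identification, reversible pseudonymization and re-identification risk
assessment for electronic health records in **HL7 FHIR (JSON)** and **HL7 CDA
(XML)**.

Secondary use of EHR data — research, public health, AI development — requires
removing or masking personal identifiers before sharing, and demonstrating
that the residual re-identification risk is acceptable. Doing this by hand is
slow and unreliable, and general-purpose anonymization tools do not understand
healthcare formats. `wisedeid` is a library and CLI for healthcare
organizations, researchers and individuals that automates the full cycle:

1. **Detect** — every leaf of a FHIR resource/Bundle or CDA document is
   classified as a *direct identifier*, *quasi-identifier*, *sensitive
   attribute*, or *other*, using a rule registry covering all 18 HIPAA Safe
   Harbor identifier categories plus value-pattern detectors (email, phone,
   SSN, dates, URLs, IPs) that catch identifiers in unexpected fields.
2. **De-identify** — a context-dependent policy applies suppression,
   generalization (date → year → 5-year band, postal → 3-character prefix,
   age → 5-year band with "90+"), and keyed reversible pseudonymization.
   Sharing with a *trusted party* keeps pseudonymous linkage; a *general
   audience* (public) release is strictly stronger everywhere.
3. **Assess & gate** — re-identification risk uses the prosecutor model:
   records are partitioned into equivalence classes by their
   (post-transformation) quasi-identifier values, each record's risk is
   `1 / |class|`, and the dataset risk is the worst case
   `max_risk = 1 / min_k |class_k|`. Risk maps to LOW (≤ 0.10, i.e. k ≥ 10),
   MEDIUM (≤ 0.34, k ≥ 3) or HIGH, and the gate enforces: trusted parties may
   receive LOW or MEDIUM, the public only LOW. On rejection the tool proposes
   the generalization steps that most increase the minimum class size and can
   apply them automatically until the gate accepts.
4. **Re-identify (authorized)** — pseudonyms are HMAC-SHA256 tokens under a
   user-held secret, stored bidirectionally in an encrypted vault, so the key
   holder — and only the key holder — can restore the original document
   exactly.

A seeded synthetic-fixture generator (Synthea-like FHIR bundles and minimal
CDA documents with a ground-truth manifest) makes every step testable offline.

## Worked example

Generate a 12-patient cohort in which all patients share one quasi-identifier
tuple (`--dup-factor 12`), then de-identify it for a trusted party:

```sh
wisedeid simulate --n 12 --seed 7 --dup-factor 12 --out corpus
echo "demo-key-material" > key.txt
wisedeid deid --input corpus/bundle-seed7.json --share trusted \
    --assert-legal-basis --key-file key.txt --vault vault.bin \
    --out deid --report report.json
```

prints

```json
{
  "gate": "ACCEPT",
  "category": "LOW",
  "max_risk": 0.08333333333333333,
  "outputs": ["deid/bundle-seed7.deid.json"]
}
```

and exits 0. All 12 patients fall into one equivalence class on
(`Patient.birthDate`, `Patient.address.postalCode`, `Patient.address.city`,
`Patient.gender`), so every record's prosecutor risk is 1/12 ≈ 0.083 ≤ 0.10 —
category LOW, gate ACCEPT. In the output, names, record numbers, telecoms and
ids are replaced by deterministic vault tokens, the birth date is generalized
to its year, and the postal code to a 3-character prefix:

```json
{
  "resourceType": "Patient",
  "id": "PSN-OTHERUNI-c08d972a0f9367cb",
  "name": [{"family": "PSN-NAME-699473a6a9989022", "given": ["PSN-NAME-da51613e2e842470"]}],
  "birthDate": "1956",
  "address": [{"city": "Haapsalu", "postalCode": "110"}],
  "gender": "male"
}
```

The same identifier always maps to the same token, so references such as
`Condition.subject.reference` still point at the right (pseudonymous)
patient. The key holder can reverse the share exactly:

```sh
wisedeid reid --input deid/bundle-seed7.deid.json --run-report report.json \
    --vault vault.bin --key-file key.txt --out restored.json
```

`restored.json` is canonically identical to the input bundle. A `--share
public` run of the same corpus suppresses all direct identifiers and postal
codes, widens dates to 5-year bands, never writes a vault, and rejects (exit
code 2) whenever the residual risk exceeds LOW — add `--auto-strengthen` to
let the tool coarsen quasi-identifiers until the public gate accepts.

Other subcommands: `wisedeid detect` (annotation report with per-label
counts), `wisedeid risk` (risk report for already de-identified inputs,
including the mandatory notice that re-identification attempts are
prohibited).

## Layout

- `src/wisedeid/formats.py` — detect/parse/flatten/reconstruct/write for FHIR JSON and CDA XML
- `src/wisedeid/detection.py` — rule registry, value patterns, classification
- `src/wisedeid/deid.py`, `src/wisedeid/vault.py` — policy, operators, pseudonym vault
- `src/wisedeid/risk.py` — equivalence classes, prosecutor risk, gate, recommendations
- `src/wisedeid/pipeline.py`, `src/wisedeid/cli.py` — workflow orchestration and CLI
- `src/wisedeid/synthetic.py` — seeded fixture generator with truth manifest
- `docs/methods.md` — models, parameters, design choices and limitations
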