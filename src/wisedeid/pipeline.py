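"""Three-step guided workflow: upload (with legal-basis assertion and
data-minimization filters) -> sharing-option selection -> de-identify, assess
risk, gate, and optionally loop on recommendations until the gate accepts.

Batch semantics: all patient-level records of one run (every Patient resource
across all input files, or each CDA document) are pooled into a single dataset
for the joint risk computation.  De-identified files are written only when the
gate accepts; the run report never contains original values of suppressed or
pseudonymized fields.
"""

from __future__ import annotations

import json
import logging
import os
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Sequence, Union

from . import deid as deid_mod
from . import risk as risk_mod
from .deid import (ActionKind, ActionPlan, DeidAction, DeidPolicy, LADDER_TOP,
                   SharingContext, default_policy, plan as make_plan)
from .detection import (AnnotatedRecord, Label, QuasiKind, Registry,
                        bundle_prefix_map, default_registry, logical_path, scan)
from .errors import (EmptySelection, MissingLegalBasis, PublicShareRefusal,
                     VaultLocked)
from .formats import (CDA_NS, EhrDocument, FlatEntry, FlatRecord, FormatKind,
                      ValueKind, detect_format, flatten, parse, reconstruct,
                      resource_type_of, split_resources, write)
from .risk import (Amendment, GateDecision, RiskCategory, RiskReport, Thresholds,
                   assess, gate as risk_gate, indexless, recommend,
                   single_record_category)
from .vault import PseudonymVault, _TOKEN_RE

logger = logging.getLogger(__name__)

_MAX_STRENGTHEN_ROUNDS = 8

# nominal per-record risks for the single-record heuristic categories
_SINGLE_RECORD_NOMINAL = {RiskCategory.LOW: 0.05, RiskCategory.MEDIUM: 0.2,
                          RiskCategory.HIGH: 1.0}


@dataclass
class RunConfig:
    inputs: Sequence[Union[str, Path, EhrDocument]]
    context: SharingContext
    legal_basis_asserted: bool = False
    registry: Optional[Registry] = None
    policy: Optional[DeidPolicy] = None
    vault_path: Optional[str] = None
    key: Optional[bytes] = None
    quasi: Union[str, Sequence[str]] = "auto"
    thresholds: Thresholds = field(default_factory=Thresholds)
    include: Optional[Sequence[str]] = None
    exclude: Optional[Sequence[str]] = None
    out_dir: Optional[str] = None
    report_path: Optional[str] = None
    auto_strengthen: bool = False
    force_report_only: bool = False
    canonical_output: bool = True


@dataclass
class RunReport:
    context: SharingContext
    files: list[dict]
    quasi_paths: list[str]
    risk: RiskReport
    gate: GateDecision
    amendments_applied: list[Amendment]
    outputs: list[str]
    exit_code: int

    def as_dict(self) -> dict:
        return {
            "context": self.context.value,
            "files": self.files,
            "quasi_paths": self.quasi_paths,
            "risk": self.risk.as_dict(),
            "gate": self.gate.value,
            "amendments_applied": [a.as_dict() for a in self.amendments_applied],
            "outputs": self.outputs,
            "exit_code": self.exit_code,
        }


# ---------------------------------------------------------------------------
# data minimization
# ---------------------------------------------------------------------------

def _cda_section_names(section) -> set[str]:
    from lxml import etree
    names = set()
    for child in section:
        local = etree.QName(child).localname
        if local == "title" and child.text:
            names.add(child.text.strip())
        if local == "code" and child.get("code"):
            names.add(child.get("code"))
    return names


def filter_sections(doc: EhrDocument, include: Optional[Sequence[str]] = None,
                    exclude: Optional[Sequence[str]] = None) -> EhrDocument:
    """Subset a document before detection (GDPR data minimization).

    For bundles, entries are kept by resource type; for CDA, sections by title
    or code.  ``include=None`` means everything; an explicitly empty selection
    is an error; excluding a type that is not present only logs a warning.
    """
    if include is not None and len(include) == 0:
        raise EmptySelection("nothing selected for sharing")
    include_all = include is None or "all" in include
    exclude = list(exclude or [])

    if doc.format is FormatKind.FHIR_JSON_BUNDLE:
        present = {e.get("resource", {}).get("resourceType") for e in doc.root.get("entry", [])}
        for name in exclude:
            if name not in present:
                logger.warning("exclude filter %r matches no bundle entry", name)
        entries = [e for e in doc.root.get("entry", [])
                   if (include_all or e.get("resource", {}).get("resourceType") in include)
                   and e.get("resource", {}).get("resourceType") not in exclude]
        if not entries:
            raise EmptySelection("section filters removed every bundle entry")
        new_root = {k: v for k, v in doc.root.items()}
        new_root["entry"] = entries
        return EhrDocument(format=doc.format, root=new_root, source_id=doc.source_id)

    if doc.format is FormatKind.FHIR_JSON_RESOURCE:
        rtype = doc.root.get("resourceType")
        if (not include_all and rtype not in include) or rtype in exclude:
            raise EmptySelection(f"resource type {rtype} not selected")
        return doc

    # CDA: filter structuredBody sections by title or code
    from copy import deepcopy
    from lxml import etree
    if include_all and not exclude:
        return doc
    root = deepcopy(doc.root)
    kept = 0
    matched_names: set[str] = set()
    for component in root.findall(f".//{{{CDA_NS}}}structuredBody/{{{CDA_NS}}}component"):
        sections = component.findall(f"{{{CDA_NS}}}section")
        for section in sections:
            names = _cda_section_names(section)
            matched_names |= names
            keep = (include_all or bool(names & set(include))) and not (names & set(exclude))
            if keep:
                kept += 1
            else:
                component.getparent().remove(component)
    for name in exclude:
        if name not in matched_names:
            logger.warning("exclude filter %r matches no CDA section", name)
    if kept == 0:
        raise EmptySelection("section filters removed every CDA section")
    return EhrDocument(format=doc.format, root=root, source_id=doc.source_id)


# ---------------------------------------------------------------------------
# pipeline internals
# ---------------------------------------------------------------------------

def _load_documents(config: RunConfig) -> list[EhrDocument]:
    docs = []
    for item in config.inputs:
        if isinstance(item, EhrDocument):
            docs.append(item)
            continue
        path = Path(item)
        raw = path.read_text(encoding="utf-8")
        fmt = detect_format(raw)
        source_id = path.stem
        docs.append(parse(raw, fmt, source_id=source_id))
    return docs


def _planned(annotated: AnnotatedRecord, context: SharingContext, policy: DeidPolicy,
             overrides: dict[str, DeidAction]) -> ActionPlan:
    base = make_plan(annotated, context, policy)
    if not overrides:
        return base
    prefixes = bundle_prefix_map(annotated.flat)
    actions = list(base.actions)
    for i, (entry, cls) in enumerate(zip(annotated.flat.entries, annotated.annotations)):
        if cls.label is not Label.QUASI:
            continue
        key = indexless(logical_path(entry.path, prefixes))
        if key in overrides:
            new = overrides[key]
            if new.strength() > actions[i].strength():
                actions[i] = new
    return ActionPlan(actions=actions, classifications=base.classifications,
                      context=context)


def _risk_records(deid_flats: Sequence[FlatRecord], registry: Registry
                  ) -> list[tuple[FlatRecord, AnnotatedRecord]]:
    """Patient-level records pooled for the joint risk computation."""
    records = []
    for flat in deid_flats:
        for rec in split_resources(flat):
            if resource_type_of(rec) in ("Patient", "ClinicalDocument"):
                records.append((rec, scan(rec, registry)))
    if not records:
        records = [(flat, scan(flat, registry)) for flat in deid_flats]
    return records


def _auto_quasi_paths(records: Sequence[tuple[FlatRecord, AnnotatedRecord]]) -> list[str]:
    paths: set[str] = set()
    for _rec, annotated in records:
        for entry, cls in annotated.entries_with(Label.QUASI):
            paths.add(indexless(entry.path))
    return sorted(paths)


def _applied_levels(plans: Sequence[ActionPlan], flats: Sequence[FlatRecord]
                    ) -> tuple[dict[str, int], dict[str, QuasiKind]]:
    levels: dict[str, int] = {}
    kinds: dict[str, QuasiKind] = {}
    for action_plan, flat in zip(plans, flats):
        prefixes = bundle_prefix_map(flat)
        for entry, action, cls in zip(flat.entries, action_plan.actions,
                                      action_plan.classifications):
            if cls.label is not Label.QUASI:
                continue
            key = indexless(logical_path(entry.path, prefixes))
            kind = cls.quasi_kind or QuasiKind.DATE
            kinds.setdefault(key, kind)
            if action.kind is ActionKind.GENERALIZE:
                lvl = action.level
            elif action.kind is ActionKind.SUPPRESS:
                lvl = LADDER_TOP.get(kind, 0)
            else:
                lvl = 0
            levels[key] = max(levels.get(key, 0), lvl)
    return levels, kinds


def run_pipeline(config: RunConfig) -> RunReport:
    """detect -> plan -> apply -> risk -> gate (-> strengthen loop).

    Exit-code contract: 0 on ACCEPT (or --force-report-only), 2 on REJECT;
    errors raise and the CLI maps them to exit 1.
    """
    if not config.legal_basis_asserted:
        raise MissingLegalBasis(
            "a legal basis for data processing must be asserted before any "
            "input is read")
    registry = config.registry or default_registry()
    policy = config.policy or default_policy()
    context = config.context

    vault: Optional[PseudonymVault] = None
    if context is SharingContext.TRUSTED_PARTY:
        if not config.key:
            raise VaultLocked("trusted-party sharing requires key material for "
                              "the pseudonym vault")
        vault = PseudonymVault.open_or_create(config.vault_path or "", config.key)

    docs = _load_documents(config)
    if config.include is not None or config.exclude:
        docs = [filter_sections(d, config.include, config.exclude) for d in docs]
    flats = [flatten(d) for d in docs]
    scans = [scan(f, registry) for f in flats]

    overrides: dict[str, DeidAction] = {}
    amendments_applied: list[Amendment] = []
    for _round in range(_MAX_STRENGTHEN_ROUNDS + 1):
        plans = [_planned(s, context, policy, overrides) for s in scans]
        deid_flats = [deid_mod.apply(f, p, vault) for f, p in zip(flats, plans)]
        records = _risk_records(deid_flats, registry)
        if config.quasi == "auto":
            quasi_paths = _auto_quasi_paths(records)
        else:
            quasi_paths = sorted(config.quasi)

        if len(records) == 1:
            category = single_record_category(records[0][1])
            nominal = _SINGLE_RECORD_NOMINAL[category]
            report = RiskReport(
                per_record_risk=[nominal], max_risk=nominal, avg_risk=nominal,
                unique_fraction=1.0 if category is RiskCategory.HIGH else 0.0,
                category=category, context=context,
                gate=risk_gate(category, context),
                quasi_paths=quasi_paths, n_records=1)
        else:
            report = assess([r for r, _ in records], quasi_paths, context,
                            config.thresholds)

        if report.gate is GateDecision.ACCEPT:
            break
        levels, kinds = _applied_levels(plans, flats)
        if len(records) > 1:
            report.recommendations = recommend(
                [r for r, _ in records], quasi_paths, kinds, context,
                levels=levels, thresholds=config.thresholds)
        else:
            report.recommendations = [Amendment(
                path="", action=None,
                note="single record retains identifying detail; strengthen the "
                     "policy or suppress remaining quasi-identifiers")]
        if not config.auto_strengthen:
            break
        actionable = [a for a in report.recommendations
                      if a.path and a.action is not None]
        if not actionable:
            break
        for a in actionable:
            overrides[a.path] = a.action
        amendments_applied.extend(actionable)

    # reporting and outputs
    files = []
    for doc, flat, annotated, action_plan in zip(docs, flats, scans, plans):
        counts = annotated.counts()
        action_counts: dict[str, int] = {}
        audit = []
        for entry, action in zip(flat.entries, action_plan.actions):
            action_counts[action.kind.value] = action_counts.get(action.kind.value, 0) + 1
            if action.kind is not ActionKind.KEEP:
                label = action.kind.value
                if action.kind is ActionKind.GENERALIZE:
                    label += f"({action.level})"
                audit.append({"path": entry.path, "action": label})
        files.append({"source_id": doc.source_id, "format": doc.format.value,
                      "n_entries": len(flat), "label_counts": counts,
                      "action_counts": action_counts, "actions": audit})

    outputs: list[str] = []
    accepted = report.gate is GateDecision.ACCEPT
    if accepted and not config.force_report_only and config.out_dir:
        os.makedirs(config.out_dir, exist_ok=True)
        for doc, deid_flat in zip(docs, deid_flats):
            out_doc = reconstruct(deid_flat)
            ext = "json" if doc.format.is_json else "xml"
            out_path = os.path.join(config.out_dir, f"{doc.source_id}.deid.{ext}")
            with open(out_path, "w", encoding="utf-8") as fh:
                fh.write(write(out_doc, canonical=config.canonical_output))
            outputs.append(out_path)

    if vault is not None:
        for doc in docs:
            vault.record_context(doc.source_id, context.value)
        if config.vault_path:
            vault.save(config.vault_path)

    exit_code = 0 if (accepted or config.force_report_only) else 2
    run_report = RunReport(context=context, files=files, quasi_paths=quasi_paths,
                           risk=report, gate=report.gate,
                           amendments_applied=amendments_applied,
                           outputs=outputs, exit_code=exit_code)
    if config.report_path:
        os.makedirs(os.path.dirname(config.report_path) or ".", exist_ok=True)
        with open(config.report_path, "w", encoding="utf-8") as fh:
            json.dump(run_report.as_dict(), fh, indent=2, sort_keys=True)
    return run_report


# ---------------------------------------------------------------------------
# authorized re-identification
# ---------------------------------------------------------------------------

def _restore_entry_value(entry: FlatEntry, vault: PseudonymVault) -> Any:
    value = entry.value
    if not isinstance(value, str) or "PSN-" not in value:
        return value
    text = value.strip()
    if _TOKEN_RE.fullmatch(text):
        original = vault.original(text)
        if "/" in original and entry.path.endswith(".id"):
            return original.split("/", 1)[1]
        return original
    m = re.match(r"^([A-Za-z]+)/(PSN-[A-Z0-9]+-[0-9a-f]{16})$", text)
    if m:
        return vault.original(m.group(2))
    return _TOKEN_RE.sub(lambda tok: vault.original(tok.group(0)), text)


def reid_pipeline(deid_path: Union[str, Path], report_path: Union[str, Path],
                  vault_path: str, key: bytes,
                  out_path: Optional[str] = None) -> EhrDocument:
    """Restore originals in a trusted-party de-identified document.

    Refuses documents shared with a general audience: public releases are
    anonymized, not pseudonymized, and must stay that way.
    """
    with open(report_path, encoding="utf-8") as fh:
        run_report = json.load(fh)
    if run_report.get("context") == SharingContext.GENERAL_AUDIENCE.value:
        raise PublicShareRefusal(
            "this document was anonymized for a general audience; "
            "re-identification is not possible and not permitted")
    vault = PseudonymVault.open(vault_path, key)

    path = Path(deid_path)
    source_id = path.stem
    if source_id.endswith(".deid"):
        source_id = source_id[: -len(".deid")]
    doc = parse(path.read_text(encoding="utf-8"), source_id=source_id)
    flat = flatten(doc)

    restored: dict[str, FlatEntry] = {}
    for e in flat.entries:
        restored[e.path] = FlatEntry(e.path, _restore_entry_value(e, vault), e.value_kind)
    for row in vault.restores_for(source_id):
        rpath, rvalue, rkind = row
        restored[rpath] = FlatEntry(rpath, rvalue, ValueKind(rkind))

    order = {p: i for i, p in enumerate(vault.orders.get(source_id, []))}
    entries = sorted(restored.values(),
                     key=lambda e: order.get(e.path, len(order) + 1))
    out_flat = FlatRecord(entries=entries, format=flat.format, source_id=source_id)
    out_doc = reconstruct(out_flat)
    if out_path:
        with open(out_path, "w", encoding="utf-8") as fh:
            fh.write(write(out_doc, canonical=True))
    return out_doc
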