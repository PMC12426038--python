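"""Reading, flattening, reconstructing and writing HL7 FHIR (JSON) and HL7 CDA (XML).

The pipeline operates on a flat view of a record: an ordered list of
``(path, value, value_kind)`` triples in depth-first document order.  Paths
are dot-separated element names with zero-based bracket indices for repeated
siblings (``Patient.name[0].given[1]``) and a trailing ``@name`` segment for
XML attributes (``...patientRole.id@extension``).  Flattening is lossless:
``reconstruct(flatten(parse(x)))`` reproduces ``x`` under canonical
serialization, and a flat record with entries removed reconstructs to a
document without those leaves (index gaps are compacted so FHIR arrays stay
dense).
"""

from __future__ import annotations

import io
import json
import logging
import re
from dataclasses import dataclass
from enum import Enum
from typing import Any, Iterator, Union

from lxml import etree

from .errors import MalformedPath, SchemaViolation, UnknownSchema, UnparseableInput

logger = logging.getLogger(__name__)

CDA_NS = "urn:hl7-org:v3"


class FormatKind(Enum):
    FHIR_JSON_RESOURCE = "fhir-json-resource"
    FHIR_JSON_BUNDLE = "fhir-json-bundle"
    CDA_XML = "cda-xml"

    @property
    def is_json(self) -> bool:
        return self in (FormatKind.FHIR_JSON_RESOURCE, FormatKind.FHIR_JSON_BUNDLE)


class ValueKind(Enum):
    TEXT = "text"
    NUMBER = "number"
    BOOLEAN = "boolean"
    ATTRIBUTE = "attribute"


@dataclass
class EhrDocument:
    """A parsed FHIR resource/Bundle (dict) or CDA document (lxml element tree)."""

    format: FormatKind
    root: Any  # dict for JSON formats, lxml Element for CDA
    source_id: str = ""

    @property
    def resource_type(self) -> str:
        if self.format.is_json:
            return self.root.get("resourceType", "")
        return etree.QName(self.root).localname


@dataclass(frozen=True)
class FlatEntry:
    path: str
    value: Any
    value_kind: ValueKind


@dataclass
class FlatRecord:
    entries: list[FlatEntry]
    format: FormatKind
    source_id: str = ""

    def __iter__(self) -> Iterator[FlatEntry]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def value_at(self, path: str) -> Any:
        for e in self.entries:
            if e.path == path:
                return e.value
        raise KeyError(path)

    def paths(self) -> list[str]:
        return [e.path for e in self.entries]


# ---------------------------------------------------------------------------
# format detection & parsing
# ---------------------------------------------------------------------------

def _as_text(raw: Union[str, bytes, io.IOBase]) -> str:
    if hasattr(raw, "read"):
        raw = raw.read()
    if isinstance(raw, bytes):
        try:
            return raw.decode("utf-8")
        except UnicodeDecodeError as exc:
            raise UnparseableInput(f"input is not UTF-8: {exc}") from exc
    return raw


def detect_format(raw: Union[str, bytes, io.IOBase]) -> FormatKind:
    """Identify an input as a single FHIR resource, a FHIR Bundle, or a CDA document."""
    text = _as_text(raw)
    if not text.strip():
        raise UnparseableInput("empty input")
    stripped = text.lstrip()
    if stripped.startswith("{") or stripped.startswith("["):
        try:
            obj = json.loads(text)
        except json.JSONDecodeError as exc:
            raise UnparseableInput(f"invalid JSON: {exc}") from exc
        if not isinstance(obj, dict) or not isinstance(obj.get("resourceType"), str) \
                or not obj.get("resourceType"):
            raise UnknownSchema("JSON input has no resourceType designator")
        if obj["resourceType"] == "Bundle":
            return FormatKind.FHIR_JSON_BUNDLE
        return FormatKind.FHIR_JSON_RESOURCE
    try:
        root = etree.fromstring(text.encode("utf-8"))
    except etree.XMLSyntaxError as exc:
        raise UnparseableInput(f"neither JSON nor well-formed XML: {exc}") from exc
    if etree.QName(root).localname == "ClinicalDocument":
        return FormatKind.CDA_XML
    raise UnknownSchema(f"XML root {root.tag!r} is not a ClinicalDocument")


def parse(raw: Union[str, bytes, io.IOBase], format: FormatKind | None = None,
          source_id: str = "") -> EhrDocument:
    """Parse raw JSON/XML into a lossless element tree.

    Ignorable whitespace between XML elements is dropped at parse time so the
    canonical serialization of the parse equals that of a flatten/reconstruct
    round trip.
    """
    text = _as_text(raw)
    if format is None:
        format = detect_format(text)
    if format.is_json:
        try:
            obj = json.loads(text)
        except json.JSONDecodeError as exc:
            raise UnparseableInput(f"invalid JSON: {exc}") from exc
        if not isinstance(obj, dict) or not obj.get("resourceType"):
            raise SchemaViolation("FHIR JSON must be an object with a resourceType")
        if format is FormatKind.FHIR_JSON_BUNDLE:
            if obj.get("resourceType") != "Bundle":
                raise SchemaViolation("declared Bundle has a different resourceType")
            if not isinstance(obj.get("entry", []), list):
                raise SchemaViolation("Bundle.entry must be a list")
        return EhrDocument(format=format, root=obj, source_id=source_id)
    parser = etree.XMLParser(remove_blank_text=True, remove_comments=True)
    try:
        root = etree.fromstring(text.encode("utf-8"), parser=parser)
    except etree.XMLSyntaxError as exc:
        raise UnparseableInput(f"invalid XML: {exc}") from exc
    if etree.QName(root).localname != "ClinicalDocument":
        raise SchemaViolation("CDA root element must be ClinicalDocument")
    return EhrDocument(format=FormatKind.CDA_XML, root=root, source_id=source_id)


def bundle_entries(doc: EhrDocument) -> list[dict]:
    """Resources contained in a Bundle's entry list (empty for non-bundles)."""
    if doc.format is not FormatKind.FHIR_JSON_BUNDLE:
        return []
    out = []
    for entry in doc.root.get("entry", []):
        res = entry.get("resource")
        if isinstance(res, dict):
            out.append(res)
    return out


# ---------------------------------------------------------------------------
# flatten
# ---------------------------------------------------------------------------

def _scalar_kind(value: Any) -> ValueKind:
    if isinstance(value, bool):
        return ValueKind.BOOLEAN
    if isinstance(value, (int, float)):
        return ValueKind.NUMBER
    return ValueKind.TEXT


def _flatten_json(node: Any, prefix: str, out: list[FlatEntry]) -> None:
    if isinstance(node, dict):
        for key, child in node.items():
            _flatten_json(child, f"{prefix}.{key}", out)
    elif isinstance(node, list):
        for i, child in enumerate(node):
            _flatten_json(child, f"{prefix}[{i}]", out)
    else:
        out.append(FlatEntry(prefix, node, _scalar_kind(node)))


def _element_text(el: etree._Element) -> str:
    # Mixed content is concatenated into a single text leaf per element.
    parts = [el.text or ""]
    for child in el:
        parts.append(child.tail or "")
    return "".join(parts).strip()


def _flatten_xml(el: etree._Element, prefix: str, out: list[FlatEntry]) -> None:
    for name in sorted(el.attrib):
        local = etree.QName(name).localname if name.startswith("{") else name
        out.append(FlatEntry(f"{prefix}@{local}", el.attrib[name], ValueKind.ATTRIBUTE))
    text = _element_text(el)
    if text:
        out.append(FlatEntry(prefix, text, ValueKind.TEXT))
    counts: dict[str, int] = {}
    for child in el:
        counts[etree.QName(child).localname] = counts.get(etree.QName(child).localname, 0) + 1
    seen: dict[str, int] = {}
    for child in el:
        name = etree.QName(child).localname
        if counts[name] > 1:
            idx = seen.get(name, 0)
            seen[name] = idx + 1
            child_prefix = f"{prefix}.{name}[{idx}]"
        else:
            child_prefix = f"{prefix}.{name}"
        _flatten_xml(child, child_prefix, out)


def flatten(doc: EhrDocument) -> FlatRecord:
    """Flatten a document to (path, value, kind) triples in depth-first order."""
    out: list[FlatEntry] = []
    if doc.format.is_json:
        root_name = doc.root["resourceType"]
        for key, child in doc.root.items():
            _flatten_json(child, f"{root_name}.{key}", out)
    else:
        _flatten_xml(doc.root, "ClinicalDocument", out)
    return FlatRecord(entries=out, format=doc.format, source_id=doc.source_id)


# ---------------------------------------------------------------------------
# path handling
# ---------------------------------------------------------------------------

_SEGMENT_RE = re.compile(r"^(?P<name>[^.\[\]@]+)(?:\[(?P<idx>\d+)\])?$")


def split_path(path: str) -> tuple[list[tuple[str, int | None]], str | None]:
    """Split a path into (name, index) segments and an optional attribute name."""
    attr = None
    if "@" in path:
        path, attr = path.rsplit("@", 1)
    segments = []
    for raw_seg in path.split("."):
        m = _SEGMENT_RE.match(raw_seg)
        if not m:
            raise MalformedPath(f"bad path segment {raw_seg!r} in {path!r}")
        idx = m.group("idx")
        segments.append((m.group("name"), int(idx) if idx is not None else None))
    return segments, attr


# ---------------------------------------------------------------------------
# reconstruct
# ---------------------------------------------------------------------------

class _JsonNode:
    """Intermediate container that can finalize into dict/list/scalar."""

    __slots__ = ("dict_children", "list_children", "value", "has_value")

    def __init__(self) -> None:
        self.dict_children: dict[str, "_JsonNode"] = {}
        self.list_children: dict[int, "_JsonNode"] = {}
        self.value: Any = None
        self.has_value = False

    def finalize(self) -> Any:
        if self.has_value:
            return self.value
        if self.list_children:
            # compact index gaps left by suppression: FHIR arrays stay dense
            return [self.list_children[i].finalize() for i in sorted(self.list_children)]
        return {k: v.finalize() for k, v in self.dict_children.items()}


def _reconstruct_json(flat: FlatRecord) -> dict:
    root = _JsonNode()
    root_name = None
    for entry in flat.entries:
        segments, attr = split_path(entry.path)
        if attr is not None:
            raise MalformedPath(f"attribute path {entry.path!r} in a JSON record")
        if root_name is None:
            root_name = segments[0][0]
        # the resource-type prefix segment names the root object; skip it
        node = root
        for name, idx in segments[1:]:
            node = node.dict_children.setdefault(name, _JsonNode())
            if idx is not None:
                node = node.list_children.setdefault(idx, _JsonNode())
        node.value = entry.value
        node.has_value = True
    obj = root.finalize()
    if not isinstance(obj, dict):
        raise MalformedPath("flat record does not reconstruct to a JSON object")
    return obj


def _reconstruct_xml(flat: FlatRecord) -> etree._Element:
    nsmap = {None: CDA_NS}
    root = etree.Element(f"{{{CDA_NS}}}ClinicalDocument", nsmap=nsmap)
    # elements are created on first touch, which is depth-first document order
    index: dict[tuple, etree._Element] = {(("ClinicalDocument", None),): root}

    def ensure(segments: tuple) -> etree._Element:
        if segments in index:
            return index[segments]
        parent = ensure(segments[:-1])
        name = segments[-1][0]
        el = etree.SubElement(parent, f"{{{CDA_NS}}}{name}")
        index[segments] = el
        return el

    for entry in flat.entries:
        segments, attr = split_path(entry.path)
        if segments[0][0] != "ClinicalDocument":
            raise MalformedPath(f"CDA path must start at ClinicalDocument: {entry.path!r}")
        key = tuple(segments)
        el = ensure(key)
        if attr is not None:
            el.set(attr, str(entry.value))
        else:
            el.text = str(entry.value)
    return root


def reconstruct(flat: FlatRecord) -> EhrDocument:
    """Rebuild a document from a flat record (possibly with entries removed).

    Array index gaps left by suppression are compacted (with no error) so the
    result is always a valid dense structure; empty containers are pruned
    because containers only exist where a surviving leaf implies them.
    """
    if flat.format.is_json:
        obj = _reconstruct_json(flat)
        return EhrDocument(format=flat.format, root=obj, source_id=flat.source_id)
    root = _reconstruct_xml(flat)
    return EhrDocument(format=FormatKind.CDA_XML, root=root, source_id=flat.source_id)


# ---------------------------------------------------------------------------
# write
# ---------------------------------------------------------------------------

def write(doc: EhrDocument, canonical: bool = False) -> str:
    """Serialize a document to text (UTF-8 content).

    Canonical mode emits sorted-key compact JSON or C14N XML so byte equality
    is meaningful across runs; non-canonical mode preserves input key order.
    """
    if doc.format.is_json:
        if canonical:
            return json.dumps(doc.root, sort_keys=True, ensure_ascii=False,
                              separators=(",", ":"))
        return json.dumps(doc.root, indent=2, ensure_ascii=False)
    if canonical:
        return etree.tostring(doc.root, method="c14n", exclusive=True).decode("utf-8")
    return etree.tostring(doc.root, pretty_print=True, encoding="unicode")


def canonical_equal(a: EhrDocument, b: EhrDocument) -> bool:
    return a.format == b.format and write(a, canonical=True) == write(b, canonical=True)


# ---------------------------------------------------------------------------
# record-level helpers
# ---------------------------------------------------------------------------

_BUNDLE_ENTRY_RE = re.compile(r"^(Bundle\.entry\[\d+\]\.resource)([.@].*)$")


def resource_type_of(flat: FlatRecord) -> str:
    if not flat.entries:
        return ""
    return flat.entries[0].path.split(".", 1)[0].split("[", 1)[0].split("@", 1)[0]


def split_resources(flat: FlatRecord) -> list[FlatRecord]:
    """Per-resource flat records: a bundle splits into its entries with paths
    rebased to their resource type; anything else passes through whole."""
    if flat.format is not FormatKind.FHIR_JSON_BUNDLE:
        return [flat]
    types: dict[str, str] = {}
    for e in flat.entries:
        if e.path.endswith(".resourceType"):
            m = _BUNDLE_ENTRY_RE.match(e.path)
            if m and m.group(2) == ".resourceType":
                types[m.group(1)] = str(e.value)
    grouped: dict[str, list[FlatEntry]] = {}
    for e in flat.entries:
        m = _BUNDLE_ENTRY_RE.match(e.path)
        if not m or m.group(1) not in types:
            continue
        prefix, rest = m.group(1), m.group(2)
        grouped.setdefault(prefix, []).append(
            FlatEntry(types[prefix] + rest, e.value, e.value_kind))
    out = []
    for i, prefix in enumerate(sorted(grouped, key=lambda p: int(re.search(r"\[(\d+)\]", p).group(1)))):
        out.append(FlatRecord(entries=grouped[prefix], format=FormatKind.FHIR_JSON_RESOURCE,
                              source_id=f"{flat.source_id}#{prefix}"))
    return out
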