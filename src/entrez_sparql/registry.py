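"""Metadata registry: parse E-utilities EInfo-dialect documents into a catalogue
of databases, their fields and their directed inter-database links.

Entrez treats *filterable* fields (usable in search terms) and *retrievable*
fields (present in fetched results) as distinct sets, and the two overlap only
partially — ``PDAT`` can be filtered but not retrieved, ``LANG`` retrieved but
not filtered.  EInfo documents declare the filterable fields and the links;
the retrievable set must be recovered from separate evidence: the result DTD
for databases that support eFetch, or a sample eSummary result document for
those that do not.  :func:`classify_retrievable` automates that second step by
collecting the leaf element names of the evidence document.

The assembled :class:`Registry` is the single source of truth for schema
generation, query validation and backend dispatch.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable

from lxml import etree

from .errors import ClassificationError, MetadataParseError, RegistryError

logger = logging.getLogger(__name__)

__all__ = [
    "FieldDescriptor",
    "LinkDescriptor",
    "DatabaseDescriptor",
    "Registry",
    "parse_einfo_master",
    "parse_einfo_db",
    "classify_retrievable",
    "build_registry",
]


@dataclass(frozen=True)
class FieldDescriptor:
    """One search/result field of a database.

    ``name`` is the short uppercase field code (``TITL``, ``PDAT``);
    ``full_name`` a human-readable label.  At least one of ``filterable`` /
    ``retrievable`` must hold — a field with neither capability is useless
    and is dropped during registry assembly.
    """

    name: str
    full_name: str
    filterable: bool = False
    retrievable: bool = False


@dataclass(frozen=True)
class LinkDescriptor:
    """A named directed relation between two databases (eLink traversable)."""

    name: str
    source_db: str
    target_db: str


@dataclass
class DatabaseDescriptor:
    name: str
    description: str = ""
    fields: list[FieldDescriptor] = field(default_factory=list)
    links: list[LinkDescriptor] = field(default_factory=list)
    supports_efetch: bool = False

    def field_map(self) -> dict[str, FieldDescriptor]:
        return {f.name: f for f in self.fields}

    def link_map(self) -> dict[str, LinkDescriptor]:
        return {l.name: l for l in self.links}

    def filterable_fields(self) -> list[str]:
        return [f.name for f in self.fields if f.filterable]

    def retrievable_fields(self) -> list[str]:
        return [f.name for f in self.fields if f.retrievable]


@dataclass
class Registry:
    """Catalogue of databases keyed by (lowercase) name."""

    databases: dict[str, DatabaseDescriptor] = field(default_factory=dict)
    generated_at: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not self.generated_at:
            self.generated_at = datetime.now(timezone.utc).isoformat()

    def __contains__(self, name: str) -> bool:
        return name in self.databases

    def __getitem__(self, name: str) -> DatabaseDescriptor:
        return self.databases[name]

    def db_names(self) -> list[str]:
        return list(self.databases)

    def links(self) -> list[LinkDescriptor]:
        return [l for db in self.databases.values() for l in db.links]

    def find_link(self, name: str) -> LinkDescriptor | None:
        for link in self.links():
            if link.name == name:
                return link
        return None

    # -- JSON cache ----------------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "generated_at": self.generated_at,
            "databases": [
                {
                    "name": db.name,
                    "description": db.description,
                    "supports_efetch": db.supports_efetch,
                    "fields": [
                        {
                            "name": f.name,
                            "full_name": f.full_name,
                            "filterable": f.filterable,
                            "retrievable": f.retrievable,
                        }
                        for f in db.fields
                    ],
                    "links": [
                        {"name": l.name, "target_db": l.target_db}
                        for l in db.links
                    ],
                }
                for db in self.databases.values()
            ],
        }
        return json.dumps(doc, indent=2, sort_keys=False)

    @classmethod
    def from_json(cls, text: str) -> "Registry":
        doc = json.loads(text)
        databases: dict[str, DatabaseDescriptor] = {}
        for d in doc["databases"]:
            databases[d["name"]] = DatabaseDescriptor(
                name=d["name"],
                description=d.get("description", ""),
                supports_efetch=d.get("supports_efetch", False),
                fields=[FieldDescriptor(**f) for f in d["fields"]],
                links=[
                    LinkDescriptor(l["name"], d["name"], l["target_db"])
                    for l in d["links"]
                ],
            )
        return cls(databases=databases, generated_at=doc.get("generated_at", ""))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "Registry":
        return cls.from_json(Path(path).read_text())


# ---------------------------------------------------------------------------
# parsing


def _parse_xml(document: str) -> etree._Element:
    try:
        return etree.fromstring(document.encode("utf-8"))
    except etree.XMLSyntaxError as exc:
        raise MetadataParseError(
            f"malformed XML at line {exc.lineno}, column {exc.position[1]}: {exc.msg}"
        ) from exc


def parse_einfo_master(document: str) -> list[str]:
    """Parse the EInfo master document into an ordered list of database names.

    Names are lowercased; duplicates are removed keeping the first occurrence.
    An empty ``DbList`` is a valid (empty) result, not an error.
    """
    root = _parse_xml(document)
    seen: dict[str, None] = {}
    for el in root.iter("DbName"):
        name = (el.text or "").strip().lower()
        if name and name not in seen:
            seen[name] = None
    return list(seen)


def parse_einfo_db(document: str) -> DatabaseDescriptor:
    """Parse a per-database EInfo document.

    Every declared field comes back ``filterable=True`` — EInfo only describes
    the search side.  Retrievable flags stay False until
    :func:`classify_retrievable` has seen the evidence document.
    """
    root = _parse_xml(document)
    name_el = root.find(".//DbName")
    if name_el is None or not (name_el.text or "").strip():
        raise MetadataParseError("EInfo document lacks a DbName element")
    db_name = name_el.text.strip().lower()
    desc_el = root.find(".//Description")
    description = (desc_el.text or "").strip() if desc_el is not None else ""

    fields: list[FieldDescriptor] = []
    seen_fields: set[str] = set()
    for f_el in root.findall(".//FieldList/Field"):
        code_el = f_el.find("Name")
        code = (code_el.text or "").strip().upper() if code_el is not None else ""
        if not code:
            logger.warning("database %s: field entry without a name skipped", db_name)
            continue
        if code in seen_fields:
            continue
        full_el = f_el.find("FullName")
        full = (full_el.text or "").strip() if full_el is not None else code
        fields.append(FieldDescriptor(code, full or code, filterable=True))
        seen_fields.add(code)

    links: list[LinkDescriptor] = []
    seen_links: set[str] = set()
    for l_el in root.findall(".//LinkList/Link"):
        lname_el = l_el.find("Name")
        target_el = l_el.find("DbTo")
        lname = (lname_el.text or "").strip() if lname_el is not None else ""
        target = (target_el.text or "").strip().lower() if target_el is not None else ""
        if not lname or not target:
            logger.warning("database %s: incomplete link entry skipped", db_name)
            continue
        if lname in seen_links:
            continue
        links.append(LinkDescriptor(lname, db_name, target))
        seen_links.add(lname)

    return DatabaseDescriptor(name=db_name, description=description,
                              fields=fields, links=links)


# ---------------------------------------------------------------------------
# retrievable classification


def _looks_like_dtd(evidence: str) -> bool:
    return "<!ELEMENT" in evidence


def _dtd_leaf_names(evidence: str) -> list[str]:
    try:
        dtd = etree.DTD(io.StringIO(evidence))
    except etree.DTDParseError as exc:
        raise ClassificationError(f"unparseable DTD evidence: {exc}") from exc
    names: list[str] = []
    for el in dtd.iterelements():
        # pcdata-only and EMPTY declarations are leaves — they carry values
        if el.type in ("mixed", "empty") or el.content is None:
            names.append(el.name.upper())
    return names


def _sample_doc_leaf_names(evidence: str) -> list[str]:
    try:
        root = etree.fromstring(evidence.encode("utf-8"))
    except etree.XMLSyntaxError as exc:
        raise ClassificationError(f"unparseable sample-document evidence: {exc}") from exc
    names: list[str] = []
    for item in root:  # one element per result item (e.g. DocSum)
        for el in item.iter():
            if el is item or len(el):
                continue
            if el.tag == "Item" and el.get("Name"):
                names.append(el.get("Name").upper())
            elif el.tag != "Id":
                names.append(str(el.tag).upper())
    return names


def classify_retrievable(descriptor: DatabaseDescriptor, evidence: str) -> DatabaseDescriptor:
    """Mark retrievable fields of ``descriptor`` from an evidence document.

    ``evidence`` is either the database's result DTD (the database supports
    eFetch) or a sample eSummary result document (it does not); the kind is
    sniffed from the content and also fixes ``supports_efetch``.  Field codes
    found in the evidence but absent from the EInfo field list are *added* as
    retrievable-only fields, labelled by their own code.
    """
    is_dtd = _looks_like_dtd(evidence)
    codes = _dtd_leaf_names(evidence) if is_dtd else _sample_doc_leaf_names(evidence)
    if not codes:
        logger.warning("database %s: evidence names zero fields", descriptor.name)

    evidence_set: dict[str, None] = {c: None for c in codes}
    known = {f.name for f in descriptor.fields}
    new_fields = [
        replace(f, retrievable=True) if f.name in evidence_set else f
        for f in descriptor.fields
    ]
    for code in evidence_set:
        if code not in known:
            new_fields.append(FieldDescriptor(code, code, filterable=False,
                                              retrievable=True))
    return DatabaseDescriptor(
        name=descriptor.name,
        description=descriptor.description,
        fields=new_fields,
        links=list(descriptor.links),
        supports_efetch=is_dtd,
    )


# ---------------------------------------------------------------------------
# assembly


def build_registry(master: str,
                   per_db: dict[str, str],
                   evidence: dict[str, str] | None = None) -> Registry:
    """Assemble a :class:`Registry` from raw metadata documents.

    Databases named in the master document but missing from ``per_db`` are
    skipped with a warning; links pointing at databases outside the final set
    are pruned; fields that end up neither filterable nor retrievable are
    dropped.  Raises :class:`RegistryError` if nothing parseable remains.
    """
    evidence = evidence or {}
    names = parse_einfo_master(master)
    databases: dict[str, DatabaseDescriptor] = {}
    for name in names:
        if name not in per_db:
            logger.warning("database %s listed in master but has no EInfo document; skipped", name)
            continue
        try:
            desc = parse_einfo_db(per_db[name])
        except MetadataParseError as exc:
            logger.warning("database %s: EInfo parse failed (%s); skipped", name, exc)
            continue
        if name in evidence:
            desc = classify_retrievable(desc, evidence[name])
        kept = []
        for f in desc.fields:
            if f.filterable or f.retrievable:
                kept.append(f)
            else:
                logger.warning("database %s: field %s is neither filterable nor retrievable; dropped",
                               name, f.name)
        desc.fields = kept
        databases[desc.name] = desc

    if not databases:
        raise RegistryError("no parseable databases: registry would be empty")

    for db in databases.values():
        pruned = []
        for link in db.links:
            if link.target_db in databases:
                pruned.append(link)
            else:
                logger.warning("link %s (%s -> %s) targets an unknown database; pruned",
                               link.name, link.source_db, link.target_db)
        db.links = pruned

    return Registry(databases=databases)
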