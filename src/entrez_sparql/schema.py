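"""RDF schema generation.

Each database becomes an RDFS class, each field a string-ranged datatype
property whose domain is its database's class, and each directed link an
object property from the source class to the target class.  RDFS cannot
express the filterable/retrievable asymmetry, so the schema ships with side
documentation (and machine-readable annotation triples) that lists, per
database, the filter-only and retrieve-only field codes.

IRIs follow a fixed convention under ``base_namespace``::

    class   <ns>Pubmed            (capitalised database name)
    field   <ns>pubmed_TITL       (dbname + "_" + field code)
    link    <ns>pubmed_gene       (link name; qualified with the source db
                                   name on collision)
    uid     <ns>uid               (binds the entry UID of any class)
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

from rdflib import Graph, Literal, Namespace, RDF, RDFS, URIRef, XSD

from .errors import SchemaError
from .registry import Registry

logger = logging.getLogger(__name__)

DEFAULT_NAMESPACE = "http://entrez-sparql.example.org/schema#"

FILTER_ONLY = "filterOnly"
RETRIEVE_ONLY = "retrieveOnly"


def class_iri(ns: str, db: str) -> URIRef:
    return URIRef(ns + db.capitalize())

def field_iri(ns: str, db: str, code: str) -> URIRef:
    return URIRef(ns + f"{db}_{code}")

def uid_iri(ns: str) -> URIRef:
    return URIRef(ns + "uid")


@dataclass
class SideDocumentation:
    """Per-database lists of filter-only and retrieve-only field codes."""

    filter_only: dict[str, list[str]] = field(default_factory=dict)
    retrieve_only: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"filter_only": self.filter_only, "retrieve_only": self.retrieve_only},
            indent=2,
        )

    def to_text(self) -> str:
        lines = ["Field asymmetry notes",
                 "=====================",
                 "",
                 "Fields listed under 'filter only' may appear in search filters but",
                 "never in retrieved results; 'retrieve only' fields are the reverse.",
                 ""]
        dbs = sorted(set(self.filter_only) | set(self.retrieve_only))
        for db in dbs:
            lines.append(f"{db}:")
            lines.append(f"  filter only:   {', '.join(self.filter_only.get(db, [])) or '-'}")
            lines.append(f"  retrieve only: {', '.join(self.retrieve_only.get(db, [])) or '-'}")
        return "\n".join(lines) + "\n"


@dataclass
class RdfSchemaDoc:
    base_namespace: str
    graph: Graph
    serialized_text: str
    classes: dict[str, URIRef]              # db name -> class IRI
    datatype_properties: dict[URIRef, tuple[str, str]]  # IRI -> (db, field code)
    object_properties: dict[URIRef, str]    # IRI -> link name

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def n_datatype_properties(self) -> int:
        return len(self.datatype_properties)

    @property
    def n_object_properties(self) -> int:
        return len(self.object_properties)


def generate_schema(registry: Registry,
                    base_namespace: str = DEFAULT_NAMESPACE,
                    fmt: str = "turtle") -> RdfSchemaDoc:
    """Generate the RDFS schema for a registry.

    Triples are inserted in a fixed (sorted) order so the serialization is
    byte-identical for equal registries.  Two links with the same name from
    different source databases collide on the IRI; the later one is qualified
    with its source database name and a warning is logged.
    """
    if not registry.databases:
        raise SchemaError("cannot generate a schema from an empty registry")

    ns = Namespace(base_namespace)
    g = Graph()
    g.bind("ez", ns)
    g.bind("rdfs", RDFS)

    classes: dict[str, URIRef] = {}
    dprops: dict[URIRef, tuple[str, str]] = {}
    oprops: dict[URIRef, str] = {}

    filter_only_iri = URIRef(base_namespace + FILTER_ONLY)
    retrieve_only_iri = URIRef(base_namespace + RETRIEVE_ONLY)
    for ann, label in ((filter_only_iri, "filter-only field"),
                       (retrieve_only_iri, "retrieve-only field")):
        g.add((ann, RDF.type, RDF.Property))
        g.add((ann, RDFS.label, Literal(label)))

    uid_prop = uid_iri(base_namespace)
    g.add((uid_prop, RDF.type, RDF.Property))
    g.add((uid_prop, RDFS.label, Literal("entry UID")))
    g.add((uid_prop, RDFS.range, XSD.string))

    for db_name in sorted(registry.databases):
        db = registry[db_name]
        c = class_iri(base_namespace, db_name)
        classes[db_name] = c
        g.add((c, RDF.type, RDFS.Class))
        g.add((c, RDFS.label, Literal(db_name)))
        if db.description:
            g.add((c, RDFS.comment, Literal(db.description)))

        for f in sorted(db.fields, key=lambda f: f.name):
            p = field_iri(base_namespace, db_name, f.name)
            dprops[p] = (db_name, f.name)
            g.add((p, RDF.type, RDF.Property))
            g.add((p, RDFS.domain, c))
            g.add((p, RDFS.range, XSD.string))
            g.add((p, RDFS.label, Literal(f.full_name)))
            if f.filterable and not f.retrievable:
                g.add((p, filter_only_iri, Literal(True)))
            if f.retrievable and not f.filterable:
                g.add((p, retrieve_only_iri, Literal(True)))

    for db_name in sorted(registry.databases):
        for link in sorted(registry[db_name].links, key=lambda l: l.name):
            p = URIRef(base_namespace + link.name)
            if p in oprops:
                qualified = URIRef(base_namespace + f"{link.source_db}_{link.name}")
                logger.warning("link IRI collision on %r; qualifying as %s",
                               link.name, qualified)
                p = qualified
            oprops[p] = link.name
            g.add((p, RDF.type, RDF.Property))
            g.add((p, RDFS.domain, classes[link.source_db]))
            g.add((p, RDFS.range, classes[link.target_db]))
            g.add((p, RDFS.label, Literal(link.name)))

    serialized = g.serialize(format=fmt)
    return RdfSchemaDoc(
        base_namespace=base_namespace,
        graph=g,
        serialized_text=serialized,
        classes=classes,
        datatype_properties=dprops,
        object_properties=oprops,
    )


def generate_side_doc(registry: Registry) -> SideDocumentation:
    """Collect the filter-only / retrieve-only field codes per database."""
    if not registry.databases:
        raise SchemaError("cannot document an empty registry")
    doc = SideDocumentation()
    for db_name in sorted(registry.databases):
        db = registry[db_name]
        fo = [f.name for f in db.fields if f.filterable and not f.retrievable]
        ro = [f.name for f in db.fields if f.retrievable and not f.filterable]
        doc.filter_only[db_name] = fo
        doc.retrieve_only[db_name] = ro
    return doc
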