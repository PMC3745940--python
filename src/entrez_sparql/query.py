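"""Query model: parse a SPARQL SELECT query and compile it into a path-shaped
chain plan over the registry.

The supported subset is deliberately small: SELECT queries whose WHERE clause
is a basic graph pattern of

* ``rdf:type`` triples declaring each instance variable's database class,
* datatype-property triples — a literal object is a *filter*, a variable
  object a *projection*,
* object-property triples joining instance variables along declared links,
* the ``uid`` property binding an entry's identifier to a variable.

FILTER, OPTIONAL, UNION, DISTINCT, aggregates and LIMIT/OFFSET are rejected
explicitly (a client-side row limit on the cursor replaces LIMIT).  The join
graph must be a simple path; its root is the endpoint carrying filters —
searching an entire database from an unfiltered root is refused.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from pyparsing import ParseException
from rdflib import Literal, URIRef, Variable
from rdflib.namespace import RDF
from rdflib.plugins.sparql import prepareQuery

from .errors import (
    AsymmetryViolationError,
    JoinShapeError,
    QueryParseError,
    SchemaMismatchError,
    UnboundedRootError,
    UnsupportedFormError,
)
from .registry import Registry
from .schema import DEFAULT_NAMESPACE

__all__ = [
    "Filter", "Projection", "QueryNode", "QueryChain", "ParsedPattern",
    "parse_query", "compile_chain", "term_expression", "chain_to_sparql",
    "explain",
]


@dataclass(frozen=True)
class Filter:
    field_code: str
    value: str


@dataclass(frozen=True)
class Projection:
    field_code: str
    variable: str


@dataclass
class QueryNode:
    db: str
    filters: list[Filter] = field(default_factory=list)
    projections: list[Projection] = field(default_factory=list)
    uid_variable: str | None = None


@dataclass
class QueryChain:
    """Ordered database nodes joined by named links; node 0 is the root."""

    nodes: list[QueryNode]
    edges: list[str]
    variables: list[str] = field(default_factory=list)  # projected, query order

    def __post_init__(self) -> None:
        assert len(self.edges) == max(len(self.nodes) - 1, 0)

    def __len__(self) -> int:
        return len(self.nodes)


@dataclass
class ParsedPattern:
    """The basic graph pattern of a SELECT query, plus bookkeeping."""

    triples: list[tuple]          # (s, p, o) rdflib terms
    projected: list[str]          # projected variable names in SELECT order
    text: str                     # raw query text (used for root tie-breaks)


_REJECTED_NODES = {
    "Filter": "FILTER",
    "LeftJoin": "OPTIONAL",
    "Union": "UNION",
    "Slice": "LIMIT/OFFSET",
    "Distinct": "DISTINCT",
    "Reduced": "REDUCED",
    "Graph": "GRAPH",
    "Minus": "MINUS",
    "AggregateJoin": "aggregates",
    "Group": "GROUP BY",
    "OrderBy": "ORDER BY",
    "ServiceGraphPattern": "SERVICE",
}


def parse_query(sparql_text: str) -> ParsedPattern:
    """Parse SPARQL text into a :class:`ParsedPattern`.

    Non-SELECT forms and constructs outside the supported subset raise
    :class:`UnsupportedFormError`; syntax errors raise
    :class:`QueryParseError` naming the position.
    """
    try:
        prepared = prepareQuery(sparql_text)
    except ParseException as exc:
        raise QueryParseError(
            f"SPARQL syntax error at line {exc.lineno}, column {exc.col}: {exc.msg}"
        ) from exc
    algebra = prepared.algebra
    if algebra.name != "SelectQuery":
        raise UnsupportedFormError(
            f"only SELECT queries are supported, got {algebra.name}")

    node = algebra.p
    while True:
        if node.name in _REJECTED_NODES:
            raise UnsupportedFormError(
                f"unsupported construct: {_REJECTED_NODES[node.name]}")
        if node.name == "BGP":
            break
        if node.name in ("Project", "ToMultiSet"):
            node = node.p
            continue
        raise UnsupportedFormError(f"unsupported query structure: {node.name}")

    projected = [str(v) for v in algebra.PV]
    return ParsedPattern(triples=list(node.triples), projected=projected,
                         text=sparql_text)


def _local_name(iri: URIRef, ns: str) -> str | None:
    s = str(iri)
    return s[len(ns):] if s.startswith(ns) else None


def _first_occurrence(text: str, var: str) -> int:
    m = re.search(r"\?" + re.escape(var) + r"\b", text)
    return m.start() if m else len(text)


def compile_chain(pattern: ParsedPattern, registry: Registry,
                  base_namespace: str = DEFAULT_NAMESPACE) -> QueryChain:
    """Compile a parsed basic graph pattern into a :class:`QueryChain`.

    Validates every class, property and link against the registry and
    enforces the filterable/retrievable asymmetry: filtering a
    non-filterable field or projecting a non-retrievable one raises
    :class:`AsymmetryViolationError` naming the field.
    """
    ns = base_namespace
    var_db: dict[str, str] = {}
    var_filters: dict[str, list[Filter]] = {}
    var_projections: dict[str, list[Projection]] = {}
    var_uid: dict[str, str] = {}
    # adjacency: frozenset{a,b} -> (src_var, link_name, dst_var)
    link_triples: list[tuple[str, str, str]] = []

    all_links = {l.name: l for l in registry.links()}
    field_triples: list[tuple[str, str, object]] = []  # (var, local, object)

    for s, p, o in pattern.triples:
        if not isinstance(s, Variable):
            raise UnsupportedFormError("triple subjects must be variables")
        svar = str(s)
        if p == RDF.type:
            local = _local_name(o, ns) if isinstance(o, URIRef) else None
            if local is None:
                raise SchemaMismatchError(f"unknown class IRI: {o}")
            db = local.lower()
            if db not in registry:
                raise SchemaMismatchError(f"class {local!r} matches no database")
            if svar in var_db and var_db[svar] != db:
                raise SchemaMismatchError(f"variable ?{svar} typed twice")
            var_db[svar] = db
            continue
        local = _local_name(p, ns) if isinstance(p, URIRef) else None
        if local is None:
            raise SchemaMismatchError(f"property outside schema namespace: {p}")
        if local == "uid":
            if not isinstance(o, Variable):
                raise UnsupportedFormError("uid must be bound to a variable")
            var_uid[svar] = str(o)
            continue
        if local in all_links:
            if not isinstance(o, Variable):
                raise UnsupportedFormError(
                    f"object property {local!r} needs a variable object")
            link_triples.append((svar, local, str(o)))
            continue
        field_triples.append((svar, local, o))

    # resolve datatype-property triples once classes are known
    for svar, local, o in field_triples:
        if svar not in var_db:
            raise SchemaMismatchError(f"variable ?{svar} has no rdf:type")
        db = var_db[svar]
        prefix = db + "_"
        if not local.startswith(prefix):
            raise SchemaMismatchError(
                f"property {local!r} does not belong to database {db!r}")
        code = local[len(prefix):]
        fmap = registry[db].field_map()
        if code not in fmap:
            raise SchemaMismatchError(
                f"database {db!r} has no field {code!r}")
        desc = fmap[code]
        if isinstance(o, Literal):
            if not desc.filterable:
                raise AsymmetryViolationError(db, code, "filter")
            var_filters.setdefault(svar, []).append(Filter(code, str(o)))
        elif isinstance(o, Variable):
            if not desc.retrievable:
                raise AsymmetryViolationError(db, code, "projection")
            var_projections.setdefault(svar, []).append(Projection(code, str(o)))
        else:
            raise UnsupportedFormError("datatype-property objects must be "
                                       "literals or variables")

    for svar, lname, ovar in link_triples:
        for v in (svar, ovar):
            if v not in var_db:
                raise SchemaMismatchError(f"variable ?{v} has no rdf:type")

    if not var_db:
        raise UnsupportedFormError("query contains no typed instance variable")

    # -- path-shape validation ----------------------------------------------
    adj: dict[str, list[tuple[str, str, bool]]] = {v: [] for v in var_db}
    for svar, lname, ovar in link_triples:
        if svar == ovar:
            raise JoinShapeError("self-link: unsupported join shape")
        adj[svar].append((ovar, lname, True))    # forward orientation
        adj[ovar].append((svar, lname, False))
    degrees = {v: len(edges) for v, edges in adj.items()}
    if any(d > 2 for d in degrees.values()):
        raise JoinShapeError("branching join: unsupported join shape")
    if len(link_triples) != len(var_db) - 1:
        raise JoinShapeError("join graph is not a simple path "
                             "(cycle or disconnected component)")
    # connectivity check via walk from an endpoint
    if len(var_db) == 1:
        order = [next(iter(var_db))]
    else:
        endpoints = [v for v, d in degrees.items() if d == 1]
        if len(endpoints) != 2:
            raise JoinShapeError("join graph is not a simple path "
                                 "(cycle or disconnected component)")
        # -- root selection ---------------------------------------------------
        filtered_eps = [v for v in endpoints if var_filters.get(v)]
        if len(filtered_eps) == 1:
            root = filtered_eps[0]
        elif len(filtered_eps) == 2:
            root = min(filtered_eps,
                       key=lambda v: _first_occurrence(pattern.text, v))
        else:
            raise UnboundedRootError(
                "neither endpoint of the chain carries a filter: "
                "unbounded root search")
        order = [root]
        prev = None
        while len(order) < len(var_db):
            cur = order[-1]
            nxts = [e for e in adj[cur] if e[0] != prev]
            nxt, lname, forward = nxts[0]
            if not forward:
                raise SchemaMismatchError(
                    f"link {lname!r} is traversed against its declared "
                    f"direction from {var_db[cur]!r}")
            prev = cur
            order.append(nxt)

    if len(var_db) == 1 and not var_filters.get(order[0]):
        raise UnboundedRootError("single-node query carries no filter: "
                                 "unbounded root search")

    # validate edge declarations along the walk
    edges: list[str] = []
    for i in range(len(order) - 1):
        a, b = order[i], order[i + 1]
        lname = next(l for s, l, o in link_triples
                     if (s, o) == (a, b))
        decl = registry[var_db[a]].link_map().get(lname)
        if decl is None or decl.target_db != var_db[b]:
            raise SchemaMismatchError(
                f"link {lname!r} is not declared from {var_db[a]!r} "
                f"to {var_db[b]!r}")
        edges.append(lname)

    # rdflib's algebra does not preserve triple order; recover declaration
    # order (it fixes the search-term rendering and projection layout) from
    # first textual occurrence in the query.
    def _literal_pos(f: Filter) -> int:
        idx = pattern.text.find(f'"{f.value}"')
        return idx if idx >= 0 else len(pattern.text)

    nodes = [
        QueryNode(
            db=var_db[v],
            filters=sorted(var_filters.get(v, []), key=_literal_pos),
            projections=sorted(
                var_projections.get(v, []),
                key=lambda p: _first_occurrence(pattern.text, p.variable)),
            uid_variable=var_uid.get(v),
        )
        for v in order
    ]
    bound: set[str] = set()
    for n in nodes:
        for pr in n.projections:
            bound.add(pr.variable)
        if n.uid_variable:
            bound.add(n.uid_variable)
    variables = [v for v in pattern.projected if v in bound]
    return QueryChain(nodes=nodes, edges=edges, variables=variables)


def term_expression(filters: list[Filter]) -> str:
    """Render filters as an Entrez search term: ``"value"[FIELD] AND ...``."""
    if not filters:
        raise ValueError("term_expression requires at least one filter "
                         "(the chain root must carry a filter)")
    return " AND ".join(f'"{f.value}"[{f.field_code}]' for f in filters)


# ---------------------------------------------------------------------------
# pretty-printing


def chain_to_sparql(chain: QueryChain,
                    base_namespace: str = DEFAULT_NAMESPACE) -> str:
    """Render a chain back to SPARQL text (inverse of compilation, modulo
    variable naming)."""
    lines = []
    varnames = [f"n{i}" for i in range(len(chain.nodes))]
    projected: list[str] = []
    for i, node in enumerate(chain.nodes):
        v = varnames[i]
        lines.append(f"  ?{v} a ez:{node.db.capitalize()} .")
        for flt in node.filters:
            lines.append(f'  ?{v} ez:{node.db}_{flt.field_code} "{flt.value}" .')
        for pr in node.projections:
            lines.append(f"  ?{v} ez:{node.db}_{pr.field_code} ?{pr.variable} .")
            projected.append(pr.variable)
        if node.uid_variable:
            lines.append(f"  ?{v} ez:uid ?{node.uid_variable} .")
            projected.append(node.uid_variable)
        if i < len(chain.edges):
            lines.append(f"  ?{v} ez:{chain.edges[i]} ?{varnames[i + 1]} .")
    select = " ".join(f"?{v}" for v in (chain.variables or projected))
    return (f"PREFIX ez: <{base_namespace}>\n"
            f"SELECT {select} WHERE {{\n" + "\n".join(lines) + "\n}\n")


def explain(chain: QueryChain) -> str:
    """One-line human-readable plan: db -link-> db -link-> db."""
    parts = [chain.nodes[0].db]
    for link, node in zip(chain.edges, chain.nodes[1:]):
        parts.append(f"-{link}->")
        parts.append(node.db)
    plan = " ".join(parts)
    root = chain.nodes[0]
    term = term_expression(root.filters) if root.filters else "(no filter)"
    return f"chain: [{plan}]\nroot search: db={root.db} term={term}\n"
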