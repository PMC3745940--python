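# Methods

## Problem setting

Entrez-style repositories expose a family of databases through four
URL-based operations: `eSearch` (UIDs of one database's entries matching a
term), `eLink` (UIDs in a second database related to one entry through a
named directed link), `eFetch`/`eSummary` (record contents for a UID list),
and a *history server* that stores a returned UID list server-side under a
`(WebEnv, query key)` pair so later requests can page through it without
re-transmission. None of these operations can join databases. This package
provides a SPARQL view over such a repository and simulates the join
client-side.

## Metadata model

A `Registry` holds, per database: its fields with independent *filterable*
and *retrievable* flags, its outgoing links `(name, source_db, target_db)`,
and whether it supports `eFetch`. EInfo-dialect documents declare only the
search side, so every field parsed from EInfo starts as filterable-only.
The retrievable set is recovered from evidence:

- for an eFetch-capable database, its result DTD — every element declared
  with `#PCDATA`-only (or `EMPTY`) content is taken as a retrievable field
  code;
- otherwise, a sample summary result document — the tag names of leaf
  elements under each result item (or the `Name` attribute for
  `Item`-style entries).

Field codes found in evidence but absent from EInfo are added as
retrieve-only fields labelled by their own code (no other label source
exists). The evidence *kind* also fixes `supports_efetch`: the protocol has
no explicit flag for it, and which kind of evidence a database yields is
exactly what distinguishes the two fetch paths. Fields that end up neither
filterable nor retrievable are dropped with a warning; links into databases
missing from the registry are pruned. Codes are normalised to upper case,
database names to lower case. The registry serializes to a single JSON
cache document; reloading it is an exact round-trip (the generation
timestamp is excluded from equality).

## Schema generation

The RDFS schema is a deterministic function of the registry: classes,
datatype properties (domain = the database's class, range `xsd:string`) and
object properties are emitted in sorted order, so equal registries yield
byte-identical Turtle. IRIs follow a fixed convention
(`<ns>Pubmed`, `<ns>pubmed_TITL`, `<ns>pubmed_gene`, plus a generic
`<ns>uid` property that binds an entry's identifier). If two source
databases declare links with the same name, the later one's IRI is
qualified with its source database name and a warning logged. RDFS cannot
state that `PDAT` may be filtered but never retrieved, or that `LANG` is
the reverse, so the schema is accompanied by side documentation (JSON +
plain text) and by annotation triples (`<ns>filterOnly`,
`<ns>retrieveOnly`) on the affected properties; query validation enforces
the same constraints mechanically.

## Query subset and compilation

Supported queries are SELECT over a basic graph pattern of `rdf:type`
triples, datatype-property triples (literal object = filter, variable
object = projection), object-property triples, and `<ns>uid` bindings.
FILTER, OPTIONAL, UNION, DISTINCT, aggregates, ORDER BY and LIMIT/OFFSET
are rejected with named errors — a client-side row limit on the cursor
replaces LIMIT, because truncating the lazy traversal is both cheaper and
exact. The instance-variable graph must be a simple path; trees, cycles and
disconnected patterns are rejected as unsupported join shapes.

Root selection: the chain must start from a filtered endpoint — an
unfiltered root would enumerate an entire database. If exactly one endpoint
carries filters it is the root; if both do, the endpoint whose variable
occurs first in the query text wins (the SPARQL algebra produced by the
parser does not preserve triple order, so textual position is the stable
proxy for "appears first"; filters and projections within a node are
likewise re-ordered by textual position so search terms render in
declaration order). Each traversed link must be declared in the walk
direction; a literal on a field that is both filterable and retrievable is
treated as a filter only, matching SQL `WHERE` semantics.

Filters render to Entrez terms as `"value"[FIELD]` conjuncts joined by
`AND`.

## Query resolution

The executor materialises the *tree of results* depth-first:

1. one `eSearch` for the root term, with the history service enabled;
2. expanding a node issues one `eLink` for its children and one batched
   fetch for the whole sibling set — a batch of *k* UIDs is one request;
3. an exhausted sibling set prunes the branch and moves the traversal up
   one level; every root-to-leaf path yields one result row.

Rows are streamed through `has_next`/`next`; `has_next` buffers exactly one
row of lookahead and is idempotent. Retained state is bounded by the *sum*
of sibling-list sizes along the current path (never the product across
levels); instrumentation records the peak and a transcript of upward moves,
which tests use to observe backtracking directly.

Design choices where the procedure was genuinely open:

- **Lazy root fetching.** A strictly eager reading of step 1 would fetch
  every root record up front; since results must be returned progressively
  and requests minimised, root records are instead fetched in batches
  (default 200) through the history key as the traversal consumes them.
  Request *timing* changes; results do not.
- **Non-root filters.** Levels below the root are populated by `eLink`,
  which cannot filter, and filter-only fields cannot be fetched for
  client-side checking. A filtered non-root node therefore triggers one
  extra `eSearch` for its `(db, term)` pair — issued once per cursor and
  cached — and child UID lists are intersected with it, preserving link
  order.
- **Fetch skipping.** A level that projects no fields needs no record
  contents, so its fetch is skipped entirely; the UID binding comes from
  the link result.
- **Duplicate rows.** Multiplicities are preserved (one row per leaf per
  path), matching SQL join semantics and the one-result-per-leaf rule.
- **Missing values.** An absent field value leaves the variable unbound
  (omitted from the row), standard SPARQL behaviour. A linked UID missing
  from its target table ("stale link") yields its row with unbound fields
  and a logged warning.
- **Ordering.** Backend-returned order is authoritative everywhere — root
  order is search order, child order is link order — which makes full query
  output byte-reproducible.

Per-cursor caches keyed on exact request arguments (search terms, link
source UIDs, record/projection pairs) guarantee no two identical backend
requests within a cursor; `request_plan_audit` recomputes the per-operation
counts from the backend's request log and checks them against the number of
distinct expanded nodes and non-empty sibling sets.

## Backends

The mock backend serves a `MockDataset` (record tables, link tables, a
history map) and is a pure function of dataset and arguments. Term matching
is case-insensitive substring per conjunct — the live service's term
semantics are richer, but substring is deterministic and sufficient to
exercise the algorithm; a conjunct naming an unknown field matches nothing,
with a warning, mirroring the live service's leniency.

The live backend builds E-utilities URLs with stdlib HTTP machinery, parses
the eSearch/eLink/eSummary XML dialects plus a generic record dialect for
eFetch, reassembles long UID lists through `retstart`/`retmax` paging,
enforces a minimum inter-request delay (default ⅓ s, the publicly
documented etiquette for unauthenticated clients) and retries transport
failures with exponential backoff. A server-side `<ERROR>` element is
surfaced verbatim. The replay server wraps a mock backend behind
`http.server` and renders the same XML dialects, so the live client's whole
path — URL, paging, history keys, parsing — runs offline; the executor is
required to produce identical rows against either backend.

## Synthetic fixtures

The generator is a pure function of its seed and emulates the structural
features the algorithm exploits: 2+ databases with reciprocal directed
links (`a_b`/`b_a` along the chain, occasional extra non-adjacent links),
4–8 fields per database of which ~30% are asymmetric by default (split
evenly between filter-only and retrieve-only), records with 1–3-word values
drawn from a 25-word pool (so single-word terms have controllable,
non-trivial selectivity), ~15% missing field values (exercising unbound
variables), per-source link fan-outs drawn from a configurable set —
{0, 1, 2, 5} by default, where 0 produces dead branches the executor must
backtrack past — and a random half of databases flagged eFetch-capable so
both fetch paths run. The manifest records exact counts as ground truth for
test oracles. Fixture directories are plain JSON plus rendered
EInfo/evidence documents, so the entire metadata pipeline runs from files.

The worked-example builder reproduces the published demonstration topology:
N root articles matching `"wilms tumor"[TITL]`, root 1 linked to exactly
one gene, that gene linked back to 557 articles (fetched in a single
batch), and every later root given live branches — so the first 557 rows
share root 1's bindings and the traversal backtracks exactly twice before
the first root-2 row. The root count is scaled to 20 (the published run
used thousands of live roots; the topology, not the volume, is what the
algorithm's behaviour depends on).

What the fixtures do *not* emulate: real Entrez term semantics (phrase
indexing, MeSH expansion, boolean grammar beyond AND), per-database result
DTD idiosyncrasies, server-side paging limits, rate-limit penalties and
live data drift. Passing tests therefore demonstrate the correctness of the
join simulation, the metadata/schema pipeline and the request-minimisation
logic — not the fidelity of any particular live database's content.

## Test and acceptance problem sizes

The oracle-equivalence suite uses 100 seeded fixtures of 2–4 databases with
up to 30 records each — small enough that the brute-force nested-loop join
is exact and instant, large enough to cover fan-out 0/1/many, shared
children, stale links, mid-chain filters and both fetch paths. The
acceptance script uses the same sizes plus the 557-leaf worked example;
end to end it runs in seconds.

## Known limitations

- SPARQL coverage is deliberately the chain-join subset; anything else is
  rejected loudly rather than approximated.
- One filter value per field conjunct, `AND`-combined; no OR/NOT ranges.
- The live backend's generic eFetch parser collects leaf elements, which is
  right for flat record dialects but lossy for deeply nested per-database
  schemas; eSummary mode is the safer default for such databases.
- The schema namespace and IRI conventions are this package's own dialect;
  no attempt is made to match any other RDF mapping of the same databases,
  and mapping onto domain ontologies (GO, FMA, PRO) is out of scope.
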