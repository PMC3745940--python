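# entrez-sparql

A SPARQL SELECT endpoint over Entrez-style biomedical databases accessed
through the E-utilities protocol (eSearch / eLink / eFetch / eSummary).

The NCBI's Entrez repository set — PubMed, Gene, Protein and some fifty
other databases — is queryable only one database at a time: the native
interface has no joins, no control over which fields come back, and no
RDF-compliant access. This package closes that gap for anyone who wants to
run cross-database queries programmatically or integrate Entrez data with
RDF infrastructure. It works in two stages:

1. **Metadata generation.** EInfo-dialect XML descriptions of the databases
   are parsed into a registry of databases, fields and directed
   inter-database links. Entrez distinguishes *filterable* fields (usable in
   search terms, e.g. `PDAT`) from *retrievable* fields (present in results,
   e.g. `LANG`), and the two sets only partially overlap; the retrievable
   set is recovered from each database's result DTD (when it supports
   eFetch) or from a sample summary document (when it does not). From the
   registry an RDFS schema is generated — one class per database, one
   string-ranged datatype property per field, one object property per link —
   plus side documentation of the filterable/retrievable asymmetry, which
   RDFS cannot express.

2. **Query resolution.** A SPARQL SELECT query written against that schema
   is compiled into a path-shaped chain of databases: literal-object triples
   become search filters, variable-object triples become projections, and
   object-property triples become eLink traversals. The chain is resolved as
   a dynamic workflow of E-utilities requests that simulates the join: the
   root database is searched once (using the history server), and each
   result is expanded depth-first through the link chain, forming a *tree of
   results* whose root-to-leaf paths are the result rows. Rows stream back
   lazily through a `has_next`/`next` cursor and serialize to SPARQL Results
   XML/JSON (or TSV). Per-cursor caches guarantee that no two identical
   backend requests are ever issued.

Two backends implement the same operation contract: a **live** client
(URL construction, XML parsing, retstart/retmax paging, history keys, rate
limiting with backoff) and an offline **mock** backed by seeded synthetic
fixtures, plus a local HTTP replay server that serves mock data in the
E-utilities XML dialects so the live client is fully exercised offline.

## Worked example

The classic three-database demonstration: articles whose title mentions
Wilms tumour, the genes related to each article, and the articles that
mention each of those genes — a single SPARQL query spanning PubMed → Gene →
PubMed:

```python
from entrez_sparql import MockBackend, run_query, worked_example_dataset

QUERY = """
PREFIX ez: <http://entrez-sparql.example.org/schema#>
SELECT ?t ?sym ?t2 WHERE {
  ?p a ez:Pubmed .
  ?p ez:pubmed_TITL "wilms tumor" .
  ?p ez:pubmed_TITL ?t .
  ?p ez:pubmed_gene ?g .
  ?g a ez:Gene .
  ?g ez:gene_SYMB ?sym .
  ?g ez:gene_pubmed ?p2 .
  ?p2 a ez:Pubmed .
  ?p2 ez:pubmed_TITL ?t2 .
}
"""

backend = MockBackend(worked_example_dataset(seed=0, n_roots=5, n_leaves=4))
variables, cursor = run_query(QUERY, backend)
rows = list(cursor)
print(variables, len(rows))
```

prints

```
['t', 'sym', 't2'] 12
```

Twelve rows, one per root-to-leaf path: the first four share article 1 and
gene WT1 (depth-first traversal exhausts one branch before backtracking),
then the cursor backtracks twice — the gene level has a single node — and
moves to the second article. `examples/` contains this and three more
narrative scripts (metadata→schema, request auditing, results
serialization); each prints the numbers it computes and what they mean.

## Command line

```sh
entrez-sparql mock-gen --seed 7 --n-dbs 3 --out fixtures/demo
entrez-sparql schema   --fixtures fixtures/demo --out schema/
entrez-sparql query    --sparql query.rq --fixtures fixtures/demo \
                       --format srj --limit 10 --audit
```

`--explain` prints the compiled chain plan without executing; validation
failures (non-path join shapes, filtering a retrieve-only field, projecting
a filter-only field) exit with the specific error name.

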