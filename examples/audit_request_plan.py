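"""Request minimisation: what a consumed cursor actually asked the backend.

Runs the three-level chain twice — once to exhaustion and once with a
client-side row limit — and prints the request audit for each.  The audit
verifies one root search (history enabled), one link call per expanded
non-leaf node, per-level batched fetches and zero duplicate requests.
"""

from entrez_sparql import (
    MockBackend,
    compile_chain,
    explain,
    open_cursor,
    parse_query,
    request_plan_audit,
    worked_example_dataset,
)

QUERY = """\
PREFIX ez: <http://entrez-sparql.example.org/schema#>
SELECT ?t ?sym ?t2 WHERE {
  ?p a ez:Pubmed . ?p ez:pubmed_TITL "wilms tumor" . ?p ez:pubmed_TITL ?t .
  ?p ez:pubmed_gene ?g . ?g a ez:Gene . ?g ez:gene_SYMB ?sym .
  ?g ez:gene_pubmed ?p2 . ?p2 a ez:Pubmed . ?p2 ez:pubmed_TITL ?t2 .
}
"""

dataset = worked_example_dataset(seed=0, n_roots=6, n_leaves=10)
chain = compile_chain(parse_query(QUERY), dataset.registry)
print(explain(chain))

backend = MockBackend(dataset)
cursor = open_cursor(chain, backend)
n_rows = sum(1 for _ in cursor)
audit = request_plan_audit(cursor)
print(f"full consumption: {n_rows} rows")
print(f"  {audit}")
print(f"  minimal request plan: {audit.minimal}")

limited_backend = MockBackend(dataset)
limited = open_cursor(chain, limited_backend, row_limit=3)
n_limited = sum(1 for _ in limited)
print(f"limited to {n_limited} rows: "
      f"{len(limited_backend.request_log)} backend requests "
      f"(vs {len(backend.request_log)} for full consumption)")

# Laziness pays: the limited cursor only expanded the branches its three
# rows lie on, leaving every other root untouched.
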