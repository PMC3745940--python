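"""A three-database chain query resolved by depth-first traversal.

The query asks for articles whose title mentions a tumour, the genes related
to each article, and the articles that mention each of those genes — a join
the native search interface cannot express.  The executor resolves it as a
dynamic workflow of search/link/fetch requests and streams rows lazily.
"""

from entrez_sparql import MockBackend, run_query, worked_example_dataset

QUERY = """\
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

dataset = worked_example_dataset(seed=0, n_roots=5, n_leaves=4)
backend = MockBackend(dataset)

variables, cursor = run_query(QUERY, backend)
print(f"projected variables: {variables}")

rows = []
while cursor.has_next():
    rows.append(cursor.next())

print(f"total rows: {len(rows)}")
for row in rows[:6]:
    print(f"  {row['sym']:6s} {row['t'][:34]:34s} -> {row['t2'][:40]}")

# Each row is one root-to-leaf path of the tree of results: an article, one
# of its related genes, and one article mentioning that gene. The first
# block of rows shares the same article and gene because the traversal is
# depth-first: it exhausts one branch before backtracking.
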