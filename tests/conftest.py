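import random

import pytest

from entrez_sparql import MockBackend, worked_example_dataset
from entrez_sparql.fixtures import WORD_POOL, generate_fixture
from entrez_sparql.query import Filter, Projection, QueryChain, QueryNode

NS = "http://entrez-sparql.example.org/schema#"

THREE_LEVEL_QUERY = """\
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


@pytest.fixture(scope="session")
def worked_example():
    """Small instance of the three-level chain topology (fast tests)."""
    return worked_example_dataset(seed=0, n_roots=5, n_leaves=9)


@pytest.fixture()
def worked_backend(worked_example):
    return MockBackend(worked_example)


def random_chain(dataset, rng: random.Random) -> QueryChain:
    """A valid chain over a generated fixture: consecutive databases of the
    pool joined by their forward links, root filtered on a pool word."""
    reg = dataset.registry
    dbs = reg.db_names()
    length = rng.randint(1, min(3, len(dbs)))
    start = rng.randrange(len(dbs) - length + 1)
    path = dbs[start:start + length]
    nodes, edges = [], []
    for i, db in enumerate(path):
        d = reg[db]
        filterable, retrievable = d.filterable_fields(), d.retrievable_fields()
        filters = []
        if i == 0:
            filters = [Filter(rng.choice(filterable), rng.choice(WORD_POOL))]
        elif rng.random() < 0.3 and filterable:
            filters = [Filter(rng.choice(filterable), rng.choice(WORD_POOL))]
        projections = [
            Projection(code, f"v{i}_{code}")
            for code in rng.sample(retrievable,
                                   min(len(retrievable), rng.randint(1, 2)))
        ]
        uid_var = f"u{i}" if rng.random() < 0.5 else None
        nodes.append(QueryNode(db=db, filters=filters,
                               projections=projections, uid_variable=uid_var))
        if i < length - 1:
            edges.append(f"{db}_{path[i + 1]}")
    variables = ([p.variable for n in nodes for p in n.projections]
                 + [n.uid_variable for n in nodes if n.uid_variable])
    return QueryChain(nodes=nodes, edges=edges, variables=variables)


def random_fixture(seed: int, rng: random.Random | None = None):
    rng = rng or random.Random(seed)
    return generate_fixture(seed, n_dbs=rng.randint(2, 4),
                            records_per_db=(1, 30), fanout=(0, 1, 2, 5))
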