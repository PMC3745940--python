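"""entrez_sparql: a SPARQL SELECT endpoint over Entrez-style E-utilities
databases.

The package has two halves.  *Metadata generation* parses EInfo-dialect
descriptions of the databases into a :class:`Registry` and derives an RDFS
schema from it (one class per database, one string datatype property per
field, one object property per directed link), together with side
documentation of the filterable/retrievable field asymmetry.  *Query
resolution* compiles a SPARQL SELECT query written against that schema into
a path-shaped chain of databases and resolves it by dynamically composing
eSearch/eLink/eFetch requests into a depth-first tree of results, streamed
back one row at a time through a ``has_next``/``next`` cursor.
"""

from .backend import (
    Backend,
    HistoryServer,
    LinkResult,
    MockBackend,
    MockDataset,
    Record,
    SearchResult,
    parse_term,
)
from .errors import EntrezSparqlError
from .executor import Cursor, RequestAudit, open_cursor, request_plan_audit
from .fixtures import (
    generate_fixture,
    load_fixture_dir,
    worked_example_dataset,
    write_fixture_dir,
)
from .query import (
    Filter,
    Projection,
    QueryChain,
    QueryNode,
    chain_to_sparql,
    compile_chain,
    explain,
    parse_query,
    term_expression,
)
from .registry import (
    DatabaseDescriptor,
    FieldDescriptor,
    LinkDescriptor,
    Registry,
    build_registry,
    classify_retrievable,
    parse_einfo_db,
    parse_einfo_master,
)
from .results import write_results
from .schema import (
    DEFAULT_NAMESPACE,
    RdfSchemaDoc,
    SideDocumentation,
    generate_schema,
    generate_side_doc,
)

__version__ = "0.1.0"


def run_query(sparql_text: str, backend: Backend,
              base_namespace: str = DEFAULT_NAMESPACE,
              fetch_batch: int = 200,
              row_limit: int | None = None) -> tuple[list[str], Cursor]:
    """Parse, validate, compile and open a cursor in one call.

    Returns the projected variable names (in query order) and the cursor.
    """
    pattern = parse_query(sparql_text)
    chain = compile_chain(pattern, backend.registry, base_namespace)
    cursor = open_cursor(chain, backend, fetch_batch=fetch_batch,
                         row_limit=row_limit)
    return chain.variables, cursor
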