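"""Depth-first chain-join executor: the "tree of results".

A compiled :class:`~entrez_sparql.query.QueryChain` is resolved against a
backend by simulating the join that E-utilities cannot express natively.
Each chain level corresponds to one database; the traversal builds the tree
of results branch by branch in depth-first order and every root-to-leaf path
is one result row.  Concretely:

1. the root database is searched once (with the history service enabled) for
   the root node's filter term;
2. expanding a node issues one eLink call for its children in the next
   database, and the whole sibling set is fetched in a single batched
   eFetch/eSummary call (only when the level actually projects fields);
3. when a sibling set is exhausted the branch is pruned and the traversal
   moves up one level — when the root list is exhausted, the cursor is done.

Rows are produced lazily through the ``has_next``/``next`` iteration schema,
so consuming the first *k* rows touches only the branches those rows lie on.
Root records are fetched in configurable batches through the history key as
the traversal consumes them.

Request minimisation: per-cursor caches keyed on the exact backend arguments
guarantee that no two identical search/link/fetch requests are ever issued;
:func:`request_plan_audit` verifies this, and the per-operation counts,
against the backend's request log.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .backend import Backend, Record
from .errors import ExhaustedCursorError
from .query import QueryChain, QueryNode, term_expression

__all__ = ["Cursor", "ResultRow", "RequestAudit", "open_cursor",
           "request_plan_audit"]

ResultRow = dict[str, str]


@dataclass
class TraversalStats:
    """Instrumentation: transcript of level moves and retained-node peaks."""

    transcript: list[tuple[str, int]] = field(default_factory=list)
    retained_nodes: int = 0
    peak_retained_nodes: int = 0
    rows_yielded: int = 0
    nonempty_sibling_sets: int = 0  # sets that needed a (possibly cached) fetch

    def retain(self, n: int) -> None:
        self.retained_nodes += n
        self.peak_retained_nodes = max(self.peak_retained_nodes,
                                       self.retained_nodes)

    def release(self, n: int) -> None:
        self.retained_nodes -= n


def _bind(node: QueryNode, uid: str, record: Record | None) -> ResultRow:
    row: ResultRow = {}
    if node.uid_variable:
        row[node.uid_variable] = uid
    if record is not None:
        for pr in node.projections:
            if pr.field_code in record.values:
                row[pr.variable] = record.values[pr.field_code]
    return row


def _needs_fetch(node: QueryNode) -> bool:
    return bool(node.projections)


class Cursor:
    """Lazy one-row-at-a-time iterator over the tree of results."""

    def __init__(self, chain: QueryChain, backend: Backend,
                 fetch_batch: int = 200, row_limit: int | None = None):
        self.chain = chain
        self.backend = backend
        self.fetch_batch = fetch_batch
        self.row_limit = row_limit
        self.stats = TraversalStats()
        self._record_cache: dict[tuple, Record] = {}
        self._link_cache: dict[tuple, tuple[str, ...]] = {}
        self._filter_cache: dict[tuple, frozenset[str]] = {}
        self._lookahead: ResultRow | None = None
        self._exhausted = False

        root = chain.nodes[0]
        result = backend.search(root.db, term_expression(root.filters),
                                history=True)
        self._root_uids = list(result.uids)
        self._history_key = result.history_key
        self._root_records: dict[str, Record] = {}
        self._root_fetched = 0
        self.stats.retain(len(self._root_uids))
        self._rows = self._walk_roots()

    # -- iteration contract --------------------------------------------------

    def has_next(self) -> bool:
        """True iff another root-to-leaf path remains.  Idempotent: repeated
        calls issue no backend requests beyond the single-row lookahead."""
        if self._lookahead is not None:
            return True
        if self._exhausted:
            return False
        if (self.row_limit is not None
                and self.stats.rows_yielded >= self.row_limit):
            self._exhausted = True
            return False
        try:
            self._lookahead = next(self._rows)
        except StopIteration:
            self._exhausted = True
            return False
        return True

    def next(self) -> ResultRow:
        if not self.has_next():
            raise ExhaustedCursorError("cursor is exhausted")
        row, self._lookahead = self._lookahead, None
        self.stats.rows_yielded += 1
        return row

    def __iter__(self):
        return self

    def __next__(self) -> ResultRow:
        if not self.has_next():
            raise StopIteration
        return self.next()

    # -- traversal -----------------------------------------------------------

    def _root_record(self, index: int, node: QueryNode) -> Record | None:
        """Fetch root records in batches through the history key, on demand."""
        if not _needs_fetch(node):
            return None
        uid = self._root_uids[index]
        if uid in self._root_records:
            return self._root_records[uid]
        start = self._root_fetched
        count = min(self.fetch_batch, len(self._root_uids) - start)
        codes = [pr.field_code for pr in node.projections]
        self.stats.nonempty_sibling_sets += 1
        batch = self.backend.fetch(node.db, None, codes,
                                   history_key=self._history_key,
                                   retstart=start, retmax=count)
        for rec in batch:
            self._root_records[rec.uid] = rec
            self._record_cache[(node.db, rec.uid, tuple(codes))] = rec
        self._root_fetched += count
        return self._root_records.get(uid)

    def _filtered_uids(self, node: QueryNode, uids: tuple[str, ...]) -> tuple[str, ...]:
        """Apply a non-root node's filters by intersecting the linked UIDs
        with one cached eSearch for the node's term (order preserved)."""
        if not node.filters:
            return uids
        key = (node.db, term_expression(node.filters))
        if key not in self._filter_cache:
            result = self.backend.search(node.db, key[1], history=False)
            self._filter_cache[key] = frozenset(result.uids)
        allowed = self._filter_cache[key]
        return tuple(u for u in uids if u in allowed)

    def _link_children(self, level: int, uid: str) -> tuple[str, ...]:
        src = self.chain.nodes[level]
        dst = self.chain.nodes[level + 1]
        link = self.chain.edges[level]
        key = (src.db, link, uid)
        if key not in self._link_cache:
            result = self.backend.link(src.db, dst.db, link, uid)
            self._link_cache[key] = result.uids
        return self._filtered_uids(dst, self._link_cache[key])

    def _fetch_level(self, node: QueryNode, uids: tuple[str, ...]) -> dict[str, Record]:
        """One batched fetch for a sibling set, minus already-cached records."""
        if not _needs_fetch(node) or not uids:
            return {}
        self.stats.nonempty_sibling_sets += 1
        codes = tuple(pr.field_code for pr in node.projections)
        missing = [u for u in uids
                   if (node.db, u, codes) not in self._record_cache]
        if missing:
            for rec in self.backend.fetch(node.db, missing, list(codes)):
                self._record_cache[(node.db, rec.uid, codes)] = rec
        return {u: self._record_cache[(node.db, u, codes)] for u in uids}

    def _walk_roots(self):
        root = self.chain.nodes[0]
        for i, uid in enumerate(self._root_uids):
            record = self._root_record(i, root)
            yield from self._walk(0, uid, record, {})
        self.stats.release(len(self._root_uids))

    def _walk(self, level: int, uid: str, record: Record | None,
              prefix: ResultRow):
        node = self.chain.nodes[level]
        bindings = dict(prefix)
        bindings.update(_bind(node, uid, record))
        if level == len(self.chain.nodes) - 1:
            self.stats.transcript.append(("row", level))
            yield bindings
            return
        children = self._link_children(level, uid)
        self.stats.retain(len(children))
        records = self._fetch_level(self.chain.nodes[level + 1], children)
        for child in children:
            yield from self._walk(level + 1, child, records.get(child),
                                  bindings)
        # sibling set exhausted: prune the branch and move up one level
        self.stats.release(len(children))
        self.stats.transcript.append(("up", level + 1))


def open_cursor(chain: QueryChain, backend: Backend,
                fetch_batch: int = 200,
                row_limit: int | None = None) -> Cursor:
    """Open a cursor: issues exactly one root search (history enabled) and
    nothing else until rows are requested."""
    return Cursor(chain, backend, fetch_batch=fetch_batch,
                  row_limit=row_limit)


# ---------------------------------------------------------------------------
# request audit


@dataclass
class RequestAudit:
    root_searches: int
    filter_searches: int
    link_calls: int
    fetch_calls: int
    duplicate_requests: int
    distinct_expanded_nonleaf: int
    nonempty_sibling_sets: int

    @property
    def minimal(self) -> bool:
        return (self.root_searches == 1
                and self.duplicate_requests == 0
                and self.link_calls == self.distinct_expanded_nonleaf
                and self.fetch_calls <= self.nonempty_sibling_sets)


def request_plan_audit(cursor: Cursor) -> RequestAudit:
    """Summarize a cursor's backend request log.

    ``minimal`` holds when there was exactly one root search, one link call
    per *distinct* expanded non-leaf node (repeats served from cache), at
    most one batched fetch per non-empty sibling set (plus the history-keyed
    root batches, counted as one set each), and no two identical requests.
    """
    log = cursor.backend.request_log
    searches = [r for r in log if r[0] == "search"]
    links = [r for r in log if r[0] == "link"]
    fetches = [r for r in log if r[0] == "fetch"]
    root = cursor.chain.nodes[0]
    root_term = term_expression(root.filters)
    root_searches = sum(
        1 for r in searches
        if dict(r[1])["db"] == root.db and dict(r[1])["term"] == root_term
        and dict(r[1])["history"]
    )
    duplicates = len(log) - len(set(log))
    return RequestAudit(
        root_searches=root_searches,
        filter_searches=len(searches) - root_searches,
        link_calls=len(links),
        fetch_calls=len(fetches),
        duplicate_requests=duplicates,
        distinct_expanded_nonleaf=len(cursor._link_cache),
        nonempty_sibling_sets=cursor.stats.nonempty_sibling_sets,
    )
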