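"""Independent brute-force oracle: exhaustive nested-loop join over a mock
dataset's tables.

This shares no code with the depth-first executor — it materialises every
root-to-leaf path by scanning the record and link tables directly — and is
used by the test suite and the acceptance script to cross-check the
executor's lazily streamed result rows, including duplicate-path
multiplicities and unbound values.
"""

from __future__ import annotations

from collections import Counter

from .backend import MockDataset, Record
from .query import QueryChain, QueryNode


def _matches_filters(node: QueryNode, record: Record | None) -> bool:
    if not node.filters:
        return True
    if record is None:
        return False
    return all(f.value.lower() in record.values.get(f.field_code, "").lower()
               for f in node.filters)


def _bindings(node: QueryNode, uid: str, record: Record | None) -> dict[str, str]:
    out: dict[str, str] = {}
    if node.uid_variable:
        out[node.uid_variable] = uid
    if record is not None:
        for pr in node.projections:
            if pr.field_code in record.values:
                out[pr.variable] = record.values[pr.field_code]
    return out


def brute_force_join(dataset: MockDataset, chain: QueryChain) -> list[dict[str, str]]:
    """Materialize every result row by nested-loop joining the fixture tables.

    A UID reachable along two different paths yields two rows; a linked UID
    missing from its target table contributes a row with only its UID
    variable bound (matching the executor's stale-link handling).
    """
    root = chain.nodes[0]
    root_table = dataset.tables.get(root.db, {})
    rows: list[dict[str, str]] = []

    def descend(level: int, uid: str, prefix: dict[str, str]) -> None:
        node = chain.nodes[level]
        record = dataset.tables.get(node.db, {}).get(uid)
        if level > 0 and not _matches_filters(node, record):
            return
        bindings = dict(prefix)
        bindings.update(_bindings(node, uid, record))
        if level == len(chain.nodes) - 1:
            rows.append(bindings)
            return
        link = chain.edges[level]
        for child in dataset.link_tables.get(link, {}).get(uid, []):
            descend(level + 1, child, bindings)

    for uid, record in root_table.items():
        if _matches_filters(root, record):
            descend(0, uid, {})
    return rows


def row_multiset(rows) -> Counter:
    """Hashable multiset view of result rows, for order-insensitive equality."""
    return Counter(tuple(sorted(r.items())) for r in rows)
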