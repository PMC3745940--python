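import random

import pytest
from hypothesis import given, settings, strategies as st

from entrez_sparql import (
    MockBackend,
    compile_chain,
    generate_fixture,
    open_cursor,
    parse_query,
    request_plan_audit,
    run_query,
    worked_example_dataset,
)
from entrez_sparql.backend import Record
from entrez_sparql.errors import ExhaustedCursorError
from entrez_sparql.testing import brute_force_join, row_multiset

from conftest import NS, THREE_LEVEL_QUERY, random_chain, random_fixture


def three_level_chain(dataset):
    return compile_chain(parse_query(THREE_LEVEL_QUERY), dataset.registry)


class TestOpenCursor:
    def test_opening_issues_exactly_one_root_search(self, worked_example):
        backend = MockBackend(worked_example)
        open_cursor(three_level_chain(worked_example), backend)
        assert [op for op, _ in backend.request_log] == ["search"]
        (_, args), = backend.request_log
        args = dict(args)
        assert args["db"] == "pubmed"
        assert args["term"] == '"wilms tumor"[TITL]'
        assert args["history"] is True

    def test_zero_root_matches_exhausts_immediately(self, worked_example):
        backend = MockBackend(worked_example)
        q = THREE_LEVEL_QUERY.replace("wilms tumor", "no such title anywhere")
        _, cursor = run_query(q, backend)
        assert not cursor.has_next()
        assert [op for op, _ in backend.request_log] == ["search"]

    def test_two_cursors_are_independent(self, worked_example):
        b1, b2 = MockBackend(worked_example), MockBackend(worked_example)
        c1 = open_cursor(three_level_chain(worked_example), b1)
        c2 = open_cursor(three_level_chain(worked_example), b2)
        c1.next()
        assert len(b1.request_log) > len(b2.request_log)
        assert c2.has_next()


class TestIteration:
    def test_has_next_is_idempotent(self, worked_backend, worked_example):
        cursor = open_cursor(three_level_chain(worked_example), worked_backend)
        assert cursor.has_next()
        log_len = len(worked_backend.request_log)
        for _ in range(10):
            assert cursor.has_next()
        assert len(worked_backend.request_log) == log_len

    def test_next_after_exhaustion_raises(self, worked_backend, worked_example):
        cursor = open_cursor(three_level_chain(worked_example), worked_backend)
        list(cursor)
        assert not cursor.has_next()
        with pytest.raises(ExhaustedCursorError):
            cursor.next()

    def test_has_next_never_flips_back_to_true(self, worked_backend,
                                               worked_example):
        cursor = open_cursor(three_level_chain(worked_example), worked_backend)
        n = sum(1 for _ in cursor)
        assert n > 0
        assert not cursor.has_next() and not cursor.has_next()

    def test_single_node_chain_rows_are_root_records_in_search_order(
            self, worked_example):
        backend = MockBackend(worked_example)
        q = (f'PREFIX ez: <{NS}> SELECT ?t ?u WHERE {{ ?p a ez:Pubmed . '
             f'?p ez:pubmed_TITL "wilms tumor" . ?p ez:pubmed_TITL ?t . '
             f'?p ez:uid ?u . }}')
        _, cursor = run_query(q, backend)
        rows = list(cursor)
        search_uids = backend.search("pubmed", '"wilms tumor"[TITL]').uids
        assert [r["u"] for r in rows] == list(search_uids)
        table = worked_example.tables["pubmed"]
        assert [r["t"] for r in rows] == \
            [table[u].values["TITL"] for u in search_uids]

    def test_row_count_matches_oracle_and_limit_truncates(self, worked_example):
        chain = three_level_chain(worked_example)
        full = list(open_cursor(chain, MockBackend(worked_example)))
        oracle = brute_force_join(worked_example, chain)
        assert len(full) == len(oracle)
        limited = list(open_cursor(chain, MockBackend(worked_example),
                                   row_limit=3))
        assert limited == full[:3]


L_LEAVES = 9


@pytest.fixture(scope="module")
def consumed():
    dataset = worked_example_dataset(seed=0, n_roots=5, n_leaves=L_LEAVES)
    backend = MockBackend(dataset)
    cursor = open_cursor(three_level_chain(dataset), backend)
    rows = []
    while cursor.has_next():
        rows.append(cursor.next())
    return dataset, backend, cursor, rows


class TestWorkedExampleTopology:
    """Three-level chain where root 1 links to exactly one mid-level node
    that links to L leaves: the first L rows share root-1 bindings, and the
    traversal backtracks twice before the first root-2 row."""

    L = L_LEAVES

    def test_first_block_shares_root1_bindings(self, consumed):
        _, _, _, rows = consumed
        first_block = rows[:self.L]
        assert len({r["t"] for r in first_block}) == 1
        assert len({r["sym"] for r in first_block}) == 1
        assert len({r["t2"] for r in first_block}) == self.L
        assert rows[self.L]["t"] != rows[0]["t"] or \
            rows[self.L]["sym"] != rows[0]["sym"]

    def test_traversal_backtracks_twice_between_blocks(self, consumed):
        _, _, cursor, _ = consumed
        transcript = cursor.stats.transcript
        row_positions = [i for i, (kind, _) in enumerate(transcript)
                         if kind == "row"]
        between = transcript[row_positions[self.L - 1] + 1:
                             row_positions[self.L]]
        assert [kind for kind, _ in between] == ["up", "up"]

    def test_leaf_block_fetched_in_one_batch(self, consumed):
        _, backend, _, _ = consumed
        fetches = [dict(args) for op, args in backend.request_log
                   if op == "fetch"]
        assert any(args["uids"] is not None and len(args["uids"]) == self.L
                   for args in fetches)


class TestLaziness:
    def test_first_row_touches_only_first_branch(self, worked_example):
        backend = MockBackend(worked_example)
        cursor = open_cursor(three_level_chain(worked_example), backend,
                             fetch_batch=1)
        cursor.next()
        links = [dict(args) for op, args in backend.request_log if op == "link"]
        # only root 1's expansion and its single gene's expansion
        assert len(links) == 2
        root1 = cursor._root_uids[0]
        assert links[0]["uid"] == root1

    def test_limit_expands_no_unvisited_sibling_branches(self, worked_example):
        chain = three_level_chain(worked_example)
        L = 9
        backend = MockBackend(worked_example)
        cursor = open_cursor(chain, backend, row_limit=L)
        rows = list(cursor)
        assert len(rows) == L  # all from root 1's single gene
        links = [dict(args) for op, args in backend.request_log if op == "link"]
        touched = {(args["link_name"], args["uid"]) for args in links}
        gene1 = worked_example.link_tables["pubmed_gene"][cursor._root_uids[0]][0]
        assert touched == {("pubmed_gene", cursor._root_uids[0]),
                           ("gene_pubmed", gene1)}


class TestBacktrackingAndEdgeCases:
    def test_dead_branch_is_skipped_without_leaf_fetches(self):
        # single root whose branch dies at level 2 (gene with no articles)
        dataset = worked_example_dataset(seed=0, n_roots=1, n_leaves=3)
        root = next(iter(dataset.link_tables["pubmed_gene"]))
        gene = dataset.link_tables["pubmed_gene"][root][0]
        dataset.link_tables["gene_pubmed"][gene] = []
        backend = MockBackend(dataset)
        cursor = open_cursor(three_level_chain(dataset), backend)
        assert not cursor.has_next()
        assert brute_force_join(dataset, cursor.chain) == []
        fetched_dbs = [dict(args)["db"] for op, args in backend.request_log
                       if op == "fetch"]
        # no leaf-level fetch happened: the only pubmed fetch is the root batch
        assert fetched_dbs.count("pubmed") == 1

    def test_stale_link_yields_row_with_unbound_leaf_fields(self):
        dataset = worked_example_dataset(seed=0, n_roots=1, n_leaves=2)
        root = next(iter(dataset.link_tables["pubmed_gene"]))
        gene = dataset.link_tables["pubmed_gene"][root][0]
        dataset.link_tables["gene_pubmed"][gene].append("999999")  # stale
        q = THREE_LEVEL_QUERY.replace("?p2 ez:pubmed_TITL ?t2 .",
                                      "?p2 ez:pubmed_TITL ?t2 . ?p2 ez:uid ?u2 .")
        q = q.replace("SELECT ?t ?sym ?t2", "SELECT ?t ?sym ?t2 ?u2")
        _, cursor = run_query(q, MockBackend(dataset))
        rows = list(cursor)
        stale = [r for r in rows if r.get("u2") == "999999"]
        assert len(stale) == 1 and "t2" not in stale[0]
        assert row_multiset(rows) == \
            row_multiset(brute_force_join(dataset, cursor.chain))

    def test_mid_chain_filter_restricts_branches(self):
        dataset = worked_example_dataset(seed=0, n_roots=5, n_leaves=4)
        q = THREE_LEVEL_QUERY.replace(
            "?g ez:gene_SYMB ?sym .",
            '?g ez:gene_SYMB ?sym . ?g ez:gene_ORGN "homo sapiens" .')
        _, cursor = run_query(q, MockBackend(dataset))
        rows = list(cursor)
        oracle = brute_force_join(dataset, cursor.chain)
        assert row_multiset(rows) == row_multiset(oracle)
        audit = request_plan_audit(cursor)
        assert audit.filter_searches == 1  # one cached search for the term


class TestRequestMinimization:
    def test_audit_on_worked_example(self, worked_example):
        backend = MockBackend(worked_example)
        cursor = open_cursor(three_level_chain(worked_example), backend)
        list(cursor)
        audit = request_plan_audit(cursor)
        assert audit.root_searches == 1
        assert audit.duplicate_requests == 0
        # closed-form: one link call per expanded non-leaf node
        expanded = sum(len(v) for v in
                       worked_example.link_tables["pubmed_gene"].values())
        assert audit.link_calls == len(cursor._root_uids) + expanded
        assert audit.minimal

    def test_shared_child_fetched_once_served_twice(self):
        dataset = worked_example_dataset(seed=0, n_roots=2, n_leaves=2)
        # both roots point at the same gene
        roots = list(dataset.link_tables["pubmed_gene"])
        shared = dataset.link_tables["pubmed_gene"][roots[0]][0]
        dataset.link_tables["pubmed_gene"][roots[1]] = [shared]
        backend = MockBackend(dataset)
        cursor = open_cursor(three_level_chain(dataset), backend)
        rows = list(cursor)
        # the shared gene appears in rows of both roots
        assert len({r["t"] for r in rows}) == 2
        gene_fetches = [dict(args) for op, args in backend.request_log
                        if op == "fetch" and dict(args)["db"] == "gene"]
        assert len(gene_fetches) == 1
        audit = request_plan_audit(cursor)
        assert audit.duplicate_requests == 0 and audit.minimal
        assert row_multiset(rows) == \
            row_multiset(brute_force_join(dataset, cursor.chain))


class TestOracleEquivalence:
    """Primary correctness surface: the executor's row multiset equals an
    exhaustive nested-loop join over the fixture tables."""

    @pytest.mark.parametrize("seed", range(25))
    def test_multiset_equals_nested_loop_join(self, seed):
        rng = random.Random(1000 + seed)
        dataset = random_fixture(seed, rng)
        chain = random_chain(dataset, rng)
        backend = MockBackend(dataset)
        cursor = open_cursor(chain, backend,
                             fetch_batch=rng.choice([1, 3, 200]))
        rows = list(cursor)
        oracle = brute_force_join(dataset, chain)
        assert row_multiset(rows) == row_multiset(oracle)
        assert request_plan_audit(cursor).minimal

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_property_next_count_equals_oracle_rows(self, seed):
        rng = random.Random(seed)
        dataset = generate_fixture(seed, n_dbs=2, records_per_db=(1, 12),
                                   fanout=(0, 1, 2))
        chain = random_chain(dataset, rng)
        backend = MockBackend(dataset)
        cursor = open_cursor(chain, backend)
        n = 0
        while cursor.has_next():
            cursor.next()
            n += 1
        assert n == len(brute_force_join(dataset, chain))


class TestMemoryContract:
    def test_peak_retained_bounded_by_sum_of_level_sizes(self, worked_example):
        backend = MockBackend(worked_example)
        cursor = open_cursor(three_level_chain(worked_example), backend)
        list(cursor)
        n_roots = len(cursor._root_uids)
        max_genes = max(len(v) for v in
                        worked_example.link_tables["pubmed_gene"].values())
        max_leaves = max(len(v) for v in
                         worked_example.link_tables["gene_pubmed"].values())
        # sum across the path, never the product
        assert cursor.stats.peak_retained_nodes <= \
            n_roots + max_genes + max_leaves
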