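"""Backend contract and the offline mock backend.

A backend exposes the three E-utilities operations the query executor needs —
``search`` (eSearch), ``link`` (eLink) and ``fetch`` (eFetch/eSummary) — plus
a request log that records every call, which is the surface on which the
request-minimisation properties are asserted.

The mock backend serves a :class:`MockDataset` of synthetic record and link
tables, and emulates the history server: a search issued with
``history=True`` stores its UID list server-side and returns an opaque
``(web environment, query key)`` pair that later fetches may page through
with ``retstart``/``retmax`` — mirroring how the live service avoids
re-transmitting long UID lists.

Mock search semantics: a term is a conjunction of ``"value"[FIELD]`` clauses;
a record matches when every clause's value occurs case-insensitively as a
substring of the record's field value.  A clause naming an unknown field
matches nothing (with a warning), mirroring Entrez leniency.
"""

from __future__ import annotations

import logging
import re
from abc import ABC, abstractmethod
from dataclasses import dataclass, field

from .errors import (
    CapabilityError,
    TermSyntaxError,
    UnknownDatabaseError,
    UnknownLinkError,
)
from .registry import Registry

logger = logging.getLogger(__name__)

HistoryKey = tuple[str, str]  # (web environment id, query key)


@dataclass(frozen=True)
class SearchResult:
    uids: tuple[str, ...]
    total_count: int
    history_key: HistoryKey | None = None


@dataclass(frozen=True)
class LinkResult:
    uids: tuple[str, ...]


@dataclass(frozen=True)
class Record:
    uid: str
    values: dict[str, str] = field(default_factory=dict)


@dataclass
class MockDataset:
    """Synthetic stand-in for a set of linked Entrez databases."""

    registry: Registry
    tables: dict[str, dict[str, Record]]          # db -> uid -> record
    link_tables: dict[str, dict[str, list[str]]]  # link name -> src uid -> targets
    summary_fields: dict[str, list[str]]          # db -> eSummary field subset
    manifest: dict


# ---------------------------------------------------------------------------
# term grammar

_CLAUSE_RE = re.compile(r'^"([^"]*)"\[([A-Za-z0-9_.-]+)\]$')


def parse_term(term: str) -> list[tuple[str, str]]:
    """Parse an Entrez term into ordered (field, value) conjuncts."""
    clauses = []
    for part in term.split(" AND "):
        m = _CLAUSE_RE.match(part.strip())
        if m is None:
            raise TermSyntaxError(f"unparseable term clause: {part!r}")
        clauses.append((m.group(2).upper(), m.group(1)))
    return clauses


class Backend(ABC):
    """E-utilities operation contract shared by the mock and live backends."""

    registry: Registry

    def __init__(self) -> None:
        self.request_log: list[tuple] = []

    def _log(self, op: str, **args) -> None:
        self.request_log.append((op, tuple(sorted(args.items()))))

    @abstractmethod
    def search(self, db: str, term: str, history: bool = False) -> SearchResult:
        ...

    @abstractmethod
    def link(self, source_db: str, target_db: str, link_name: str,
             uid: str) -> LinkResult:
        ...

    @abstractmethod
    def fetch(self, db: str, uids: list[str] | None, fields: list[str],
              history_key: HistoryKey | None = None,
              retstart: int = 0, retmax: int | None = None) -> list[Record]:
        """Fetch records by explicit UID list or by history key window.

        One call is one backend request regardless of batch size.
        """


class HistoryServer:
    """In-memory stand-in for the E-utilities history service."""

    def __init__(self) -> None:
        self._store: dict[HistoryKey, tuple[str, ...]] = {}
        self._counter = 0

    def store(self, uids: tuple[str, ...]) -> HistoryKey:
        self._counter += 1
        key = (f"MCID_{self._counter:04d}", str(self._counter))
        self._store[key] = uids
        return key

    def get(self, key: HistoryKey) -> tuple[str, ...]:
        return self._store[key]


class MockBackend(Backend):
    """Pure-function backend over a :class:`MockDataset` (plus history state)."""

    def __init__(self, dataset: MockDataset) -> None:
        super().__init__()
        self.dataset = dataset
        self.registry = dataset.registry
        self.history = HistoryServer()

    # -- operations ----------------------------------------------------------

    def search(self, db: str, term: str, history: bool = False) -> SearchResult:
        self._log("search", db=db, term=term, history=history)
        return self._search_impl(db, term, history)

    def _search_impl(self, db: str, term: str, history: bool) -> SearchResult:
        if db not in self.registry:
            raise UnknownDatabaseError(f"unknown database: {db!r}")
        clauses = parse_term(term)
        known = set(self.registry[db].field_map())
        for code, _ in clauses:
            if code not in known:
                logger.warning("search on %s: unknown field %s in term; "
                               "empty result", db, code)
        uids = tuple(
            uid for uid, rec in self.dataset.tables.get(db, {}).items()
            if all(code in known and value.lower() in rec.values.get(code, "").lower()
                   for code, value in clauses)
        )
        key = self.history.store(uids) if history else None
        return SearchResult(uids=uids, total_count=len(uids), history_key=key)

    def link(self, source_db: str, target_db: str, link_name: str,
             uid: str) -> LinkResult:
        self._log("link", source_db=source_db, target_db=target_db,
                  link_name=link_name, uid=uid)
        if source_db not in self.registry:
            raise UnknownDatabaseError(f"unknown database: {source_db!r}")
        decl = self.registry[source_db].link_map().get(link_name)
        if decl is None or decl.target_db != target_db:
            raise UnknownLinkError(
                f"link {link_name!r} is not declared from {source_db!r} "
                f"to {target_db!r}")
        targets = self.dataset.link_tables.get(link_name, {}).get(uid, [])
        return LinkResult(uids=tuple(targets))

    def fetch(self, db: str, uids: list[str] | None, fields: list[str],
              history_key: HistoryKey | None = None,
              retstart: int = 0, retmax: int | None = None) -> list[Record]:
        self._log("fetch", db=db,
                  uids=tuple(uids) if uids is not None else None,
                  fields=tuple(fields), history_key=history_key,
                  retstart=retstart, retmax=retmax)
        if db not in self.registry:
            raise UnknownDatabaseError(f"unknown database: {db!r}")
        if uids is None:
            if history_key is None:
                raise CapabilityError("fetch needs either uids or a history key")
            stored = self.history.get(history_key)
            stop = None if retmax is None else retstart + retmax
            uids = list(stored[retstart:stop])

        desc = self.registry[db]
        if desc.supports_efetch:
            available = None  # eFetch exposes every stored field
        else:
            available = set(self.dataset.summary_fields.get(db, []))
        table = self.dataset.tables.get(db, {})
        out: list[Record] = []
        for uid in uids:
            rec = table.get(uid)
            if rec is None:
                logger.warning("fetch on %s: unknown uid %s", db, uid)
                out.append(Record(uid=uid, values={}))
                continue
            values = {
                code: rec.values[code]
                for code in fields
                if code in rec.values
                and (available is None or code in available)
            }
            out.append(Record(uid=uid, values=values))
        return out
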