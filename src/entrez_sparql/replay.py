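"""Local replay server: serves a mock dataset over HTTP in the E-utilities
XML dialects.

Wraps a :class:`~entrez_sparql.backend.MockBackend` behind a stdlib HTTP
server exposing ``esearch.fcgi``, ``elink.fcgi``, ``esummary.fcgi`` and
``efetch.fcgi``, so the live transport's URL construction and XML parsing
can be exercised offline, and backend substitutability (mock vs live over
recorded responses) can be asserted end to end.
"""

from __future__ import annotations

import threading
import urllib.parse
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer
from xml.sax.saxutils import escape

from .backend import MockBackend, MockDataset


def _render_esearch(result, retstart: int, retmax: int) -> str:
    window = result.uids[retstart:retstart + retmax]
    ids = "".join(f"<Id>{escape(u)}</Id>" for u in window)
    history = ""
    if result.history_key:
        webenv, qkey = result.history_key
        history = (f"<WebEnv>{escape(webenv)}</WebEnv>"
                   f"<QueryKey>{escape(qkey)}</QueryKey>")
    return (f"<eSearchResult><Count>{result.total_count}</Count>"
            f"<IdList>{ids}</IdList>{history}</eSearchResult>")


def _render_elink(source_db: str, target_db: str, link_name: str,
                  result) -> str:
    links = "".join(f"<Link><Id>{escape(u)}</Id></Link>" for u in result.uids)
    return (f"<eLinkResult><LinkSet><DbFrom>{escape(source_db)}</DbFrom>"
            f"<LinkSetDb><DbTo>{escape(target_db)}</DbTo>"
            f"<LinkName>{escape(link_name)}</LinkName>{links}</LinkSetDb>"
            "</LinkSet></eLinkResult>")


def _render_esummary(records) -> str:
    docs = []
    for rec in records:
        items = "".join(
            f'<Item Name="{escape(c)}" Type="String">{escape(v)}</Item>'
            for c, v in rec.values.items())
        docs.append(f"<DocSum><Id>{escape(rec.uid)}</Id>{items}</DocSum>")
    return f"<eSummaryResult>{''.join(docs)}</eSummaryResult>"


def _render_efetch(records) -> str:
    recs = []
    for rec in records:
        fields = "".join(f"<{c}>{escape(v)}</{c}>"
                         for c, v in rec.values.items())
        recs.append(f'<Record uid="{escape(rec.uid)}">{fields}</Record>')
    return f"<FetchResult>{''.join(recs)}</FetchResult>"


class _Handler(BaseHTTPRequestHandler):
    backend: MockBackend  # set on the subclass by serve_dataset

    def log_message(self, *args) -> None:  # quiet
        pass

    def do_GET(self) -> None:
        parsed = urllib.parse.urlparse(self.path)
        params = {k: v[0] for k, v in
                  urllib.parse.parse_qs(parsed.query).items()}
        endpoint = parsed.path.rsplit("/", 1)[-1]
        try:
            body = self._dispatch(endpoint, params)
            status = 200
        except Exception as exc:  # surfaced verbatim to the client
            body = f"<eResult><ERROR>{escape(str(exc))}</ERROR></eResult>"
            status = 200
        data = body.encode("utf-8")
        self.send_response(status)
        self.send_header("Content-Type", "text/xml")
        self.send_header("Content-Length", str(len(data)))
        self.end_headers()
        self.wfile.write(data)

    def _dispatch(self, endpoint: str, params: dict) -> str:
        backend = self.backend
        if endpoint == "esearch.fcgi":
            result = backend.search(params["db"], params["term"],
                                    history=params.get("usehistory") == "y")
            return _render_esearch(result,
                                   int(params.get("retstart", 0)),
                                   int(params.get("retmax", 10000)))
        if endpoint == "elink.fcgi":
            result = backend.link(params["dbfrom"], params["db"],
                                  params["linkname"], params["id"])
            return _render_elink(params["dbfrom"], params["db"],
                                 params["linkname"], result)
        if endpoint in ("esummary.fcgi", "efetch.fcgi"):
            db = params["db"]
            all_fields = list(backend.registry[db].field_map())
            if "id" in params:
                records = backend.fetch(db, params["id"].split(","), all_fields)
            else:
                key = (params["WebEnv"], params["query_key"])
                retmax = params.get("retmax")
                records = backend.fetch(
                    db, None, all_fields, history_key=key,
                    retstart=int(params.get("retstart", 0)),
                    retmax=int(retmax) if retmax is not None else None)
            if endpoint == "efetch.fcgi":
                return _render_efetch(records)
            return _render_esummary(records)
        raise ValueError(f"unknown endpoint: {endpoint}")


class ReplayServer:
    """Context manager serving a dataset on an ephemeral localhost port."""

    def __init__(self, dataset: MockDataset):
        self.backend = MockBackend(dataset)
        handler = type("Handler", (_Handler,), {"backend": self.backend})
        self._server = ThreadingHTTPServer(("127.0.0.1", 0), handler)
        self._thread = threading.Thread(target=self._server.serve_forever,
                                        daemon=True)

    @property
    def base_url(self) -> str:
        host, port = self._server.server_address[:2]
        return f"http://{host}:{port}/entrez/eutils"

    def __enter__(self) -> "ReplayServer":
        self._thread.start()
        return self

    def __exit__(self, *exc) -> None:
        self._server.shutdown()
        self._server.server_close()
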