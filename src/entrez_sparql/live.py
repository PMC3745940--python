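"""Live E-utilities transport over HTTP.

Builds esearch/elink/esummary/efetch URLs, parses the returned XML dialects
into the backend result types, enforces a minimum inter-request delay
(public NCBI etiquette: three requests per second) and retries transport
failures with exponential backoff.  The same client drives the local replay
server used in offline tests, so the URL and XML handling is exercised
without a network.
"""

from __future__ import annotations

import logging
import time
import urllib.error
import urllib.parse
import urllib.request

from lxml import etree

from .backend import Backend, HistoryKey, LinkResult, Record, SearchResult
from .errors import TransportError
from .registry import Registry

logger = logging.getLogger(__name__)


class LiveBackend(Backend):
    """E-utilities client speaking the esearch/elink/esummary/efetch dialects."""

    def __init__(self, base_url: str, registry: Registry,
                 min_delay: float = 1 / 3, retries: int = 3,
                 page_size: int = 500):
        super().__init__()
        self.base_url = base_url.rstrip("/")
        self.registry = registry
        self.min_delay = min_delay
        self.retries = retries
        self.page_size = page_size
        self._last_request = 0.0

    # -- transport -----------------------------------------------------------

    def _get(self, endpoint: str, params: dict) -> etree._Element:
        query = urllib.parse.urlencode(
            {k: v for k, v in params.items() if v is not None})
        url = f"{self.base_url}/{endpoint}.fcgi?{query}"
        delay = self.min_delay - (time.monotonic() - self._last_request)
        if delay > 0:
            time.sleep(delay)
        backoff = 0.5
        for attempt in range(self.retries + 1):
            try:
                self._last_request = time.monotonic()
                with urllib.request.urlopen(url, timeout=30) as resp:
                    body = resp.read()
                break
            except (urllib.error.URLError, OSError) as exc:
                if attempt == self.retries:
                    raise TransportError(f"request failed after "
                                         f"{self.retries + 1} attempts: {exc}") from exc
                logger.warning("transport error (%s); retrying in %.1fs", exc, backoff)
                time.sleep(backoff)
                backoff *= 2
        try:
            root = etree.fromstring(body)
        except etree.XMLSyntaxError as exc:
            raise TransportError(f"server returned invalid XML: {exc}") from exc
        err = root.find(".//ERROR")
        if err is not None:
            raise TransportError(f"server error: {err.text}")
        return root

    # -- operations ----------------------------------------------------------

    def search(self, db: str, term: str, history: bool = False) -> SearchResult:
        self._log("search", db=db, term=term, history=history)
        params = {"db": db, "term": term, "retstart": 0,
                  "retmax": self.page_size,
                  "usehistory": "y" if history else None}
        root = self._get("esearch", params)
        count = int(root.findtext("Count", "0"))
        uids = [el.text for el in root.findall(".//IdList/Id")]
        webenv = root.findtext("WebEnv")
        qkey = root.findtext("QueryKey")
        # reassemble long UID lists through retstart/retmax paging
        while len(uids) < count:
            params["retstart"] = len(uids)
            params["usehistory"] = None
            page = self._get("esearch", params)
            page_uids = [el.text for el in page.findall(".//IdList/Id")]
            if not page_uids:
                break
            uids.extend(page_uids)
        key: HistoryKey | None = (webenv, qkey) if webenv and qkey else None
        return SearchResult(uids=tuple(uids), total_count=count, history_key=key)

    def link(self, source_db: str, target_db: str, link_name: str,
             uid: str) -> LinkResult:
        self._log("link", source_db=source_db, target_db=target_db,
                  link_name=link_name, uid=uid)
        root = self._get("elink", {"dbfrom": source_db, "db": target_db,
                                   "linkname": link_name, "id": uid})
        uids = [el.text for el in root.findall(".//LinkSetDb/Link/Id")]
        return LinkResult(uids=tuple(uids))

    def fetch(self, db: str, uids: list[str] | None, fields: list[str],
              history_key: HistoryKey | None = None,
              retstart: int = 0, retmax: int | None = None) -> list[Record]:
        self._log("fetch", db=db,
                  uids=tuple(uids) if uids is not None else None,
                  fields=tuple(fields), history_key=history_key,
                  retstart=retstart, retmax=retmax)
        endpoint = "efetch" if self.registry[db].supports_efetch else "esummary"
        params: dict = {"db": db, "retmode": "xml"}
        if uids is not None:
            params["id"] = ",".join(uids)
        else:
            params["WebEnv"], params["query_key"] = history_key
            params["retstart"] = retstart
            if retmax is not None:
                params["retmax"] = retmax
        root = self._get(endpoint, params)
        wanted = set(fields)
        records = []
        for item in root:
            uid = item.get("uid") or item.findtext("Id") or ""
            values: dict[str, str] = {}
            for el in item.iter():
                if el is item or len(el):
                    continue
                code = (el.get("Name") if el.tag == "Item" else str(el.tag)).upper()
                if code in wanted and el.text is not None:
                    values[code] = el.text
            records.append(Record(uid=uid, values=values))
        by_uid = {r.uid: r for r in records}
        if uids is not None:
            return [by_uid.get(u, Record(uid=u, values={})) for u in uids]
        return records
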