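"""Streaming serialization of result rows in SPARQL Results formats.

Three formats are supported: SPARQL Results XML (``srx``, the canonical
output), SPARQL Results JSON (``srj``) and tab-separated values (``tsv``).
Writers stream: each row is serialized to the sink as soon as the cursor
produces it, honouring progressive result return.  Unbound variables are
simply absent from a solution (XML/JSON); in TSV they become empty cells,
which conflates them with empty strings — documented limitation of that
format.
"""

from __future__ import annotations

import json
from typing import IO, Iterable
from xml.sax.saxutils import escape, quoteattr

from .errors import EntrezSparqlError

FORMATS = ("srx", "srj", "tsv")


class _CountingSink:
    def __init__(self, sink: IO[str]):
        self._sink = sink
        self.count = 0

    def write(self, text: str) -> None:
        self._sink.write(text)
        self.count += len(text.encode("utf-8"))


def write_results(rows: Iterable[dict[str, str]], variables: list[str],
                  fmt: str, sink: IO[str]) -> int:
    """Serialize ``rows`` to ``sink``; returns the number of bytes written."""
    if fmt not in FORMATS:
        raise EntrezSparqlError(f"unsupported results format: {fmt!r}")
    out = _CountingSink(sink)
    if fmt == "srx":
        _write_xml(rows, variables, out)
    elif fmt == "srj":
        _write_json(rows, variables, out)
    else:
        _write_tsv(rows, variables, out)
    return out.count


def _write_xml(rows, variables, out) -> None:
    out.write('<?xml version="1.0"?>\n'
              '<sparql xmlns="http://www.w3.org/2005/sparql-results#">\n'
              '  <head>\n')
    for v in variables:
        out.write(f"    <variable name={quoteattr(v)}/>\n")
    out.write("  </head>\n  <results>\n")
    for row in rows:
        out.write("    <result>\n")
        for v in variables:
            if v in row:
                out.write(f"      <binding name={quoteattr(v)}>"
                          f"<literal>{escape(row[v])}</literal></binding>\n")
        out.write("    </result>\n")
    out.write("  </results>\n</sparql>\n")


def _write_json(rows, variables, out) -> None:
    out.write('{"head": {"vars": ' + json.dumps(variables)
              + '},\n "results": {"bindings": [\n')
    first = True
    for row in rows:
        solution = {v: {"type": "literal", "value": row[v]}
                    for v in variables if v in row}
        out.write(("" if first else ",\n") + "  " + json.dumps(solution))
        first = False
    out.write("\n]}}\n")


def _write_tsv(rows, variables, out) -> None:
    out.write("\t".join(f"?{v}" for v in variables) + "\n")
    for row in rows:
        out.write("\t".join(row.get(v, "") for v in variables) + "\n")
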