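"""Exception hierarchy.

Every error raised by this package derives from :class:`EntrezSparqlError`
so callers can catch the whole family at the CLI boundary.
"""


class EntrezSparqlError(Exception):
    """Base class for all errors raised by entrez_sparql."""


# -- metadata / registry -----------------------------------------------------

class MetadataParseError(EntrezSparqlError):
    """Malformed EInfo-dialect XML (message names the position)."""


class ClassificationError(EntrezSparqlError):
    """Unparseable retrievable-field evidence (DTD or sample document)."""


class RegistryError(EntrezSparqlError):
    """No usable database descriptions could be assembled."""


# -- schema ------------------------------------------------------------------

class SchemaError(EntrezSparqlError):
    """Schema generation failed (e.g. empty registry)."""


# -- query model -------------------------------------------------------------

class QueryParseError(EntrezSparqlError):
    """SPARQL syntax error; message carries the parser's position."""


class UnsupportedFormError(EntrezSparqlError):
    """Query form or construct outside the supported SELECT/BGP subset."""


class JoinShapeError(EntrezSparqlError):
    """The instance-variable graph is not a simple path."""


class SchemaMismatchError(EntrezSparqlError):
    """Query references a class, property or link absent from the registry."""


class AsymmetryViolationError(EntrezSparqlError):
    """Filter on a non-filterable field or projection of a non-retrievable field."""

    def __init__(self, db: str, field: str, kind: str):
        self.db = db
        self.field = field
        self.kind = kind  # "filter" or "projection"
        super().__init__(
            f"asymmetry violation: {kind} uses field {field!r} of database "
            f"{db!r}, which is not {'filterable' if kind == 'filter' else 'retrievable'}"
        )


class UnboundedRootError(EntrezSparqlError):
    """Neither endpoint of the query chain carries a filter."""


# -- backend -----------------------------------------------------------------

class BackendError(EntrezSparqlError):
    """Generic backend failure."""


class UnknownDatabaseError(BackendError):
    pass


class UnknownLinkError(BackendError):
    pass


class CapabilityError(BackendError):
    """Database supports neither eFetch nor eSummary for the request."""


class TermSyntaxError(BackendError):
    """Search term does not match the Entrez term grammar subset."""


class FixtureError(EntrezSparqlError):
    """Invalid synthetic-fixture parameters or corrupt fixture directory."""


class TransportError(BackendError):
    """HTTP/network failure in the live transport (retriable)."""


# -- executor ----------------------------------------------------------------

class ExhaustedCursorError(EntrezSparqlError):
    """next() called on a cursor whose result set is exhausted."""
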