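"""Metadata generation: from EInfo-dialect documents to an RDFS schema.

Builds a synthetic two-database repository, renders its EInfo metadata
documents and retrievable-field evidence (a result DTD for the eFetch-capable
database, a sample summary document for the other), assembles the registry
and generates the RDF schema plus the side documentation of the
filterable/retrievable asymmetry.
"""

from entrez_sparql import build_registry, generate_schema, generate_side_doc
from entrez_sparql.fixtures import (
    render_einfo_db,
    render_einfo_master,
    render_evidence,
    worked_example_dataset,
)

dataset = worked_example_dataset(seed=0, n_roots=3, n_leaves=3)
source = dataset.registry

master = render_einfo_master(source)
per_db = {name: render_einfo_db(source[name]) for name in source.db_names()}
evidence = {name: render_evidence(source[name]) for name in source.db_names()}

registry = build_registry(master, per_db, evidence)
schema = generate_schema(registry)
side = generate_side_doc(registry)

print(f"databases: {registry.db_names()}")
print(f"schema: {schema.n_classes} classes, "
      f"{schema.n_datatype_properties} datatype properties, "
      f"{schema.n_object_properties} object properties")
print(f"pubmed filter-only fields:   {side.filter_only['pubmed']}")
print(f"pubmed retrieve-only fields: {side.retrieve_only['pubmed']}")
print()
print(schema.serialized_text[:600])

# One class per database, one string property per field, one object property
# per directed link. PDAT can constrain a search but never appears in
# results; LANG is the reverse -- the side documentation records what the
# RDFS schema cannot express.
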