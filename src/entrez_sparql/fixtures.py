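"""Seeded synthetic fixtures: linked mock databases with ground-truth manifest.

The generator emulates the structural features of the Entrez repository set
that the query-resolution algorithm exploits:

* several databases with named *directed* links between them, including at
  least one reciprocal pair (``a_b`` / ``b_a``) whenever there are two or
  more databases;
* per-database field sets in which filterable and retrievable fields only
  partially overlap (``PDAT``-style filter-only and ``LANG``-style
  retrieve-only fields);
* link tables with variable fan-out — 0 (dead branches the executor must
  backtrack past), 1 and many;
* field values drawn from a small word pool so search terms have
  controllable selectivity.

Everything is a pure function of the seed; the manifest records exact counts
so test oracles can read ground truth instead of re-deriving it.

:func:`worked_example_dataset` builds the three-level chain topology of the
classic demonstration query (articles about a tumour, their related genes,
and the articles mentioning those genes): the first root links to exactly one
gene, which links back to 557 articles, so the first 557 result rows share
the root-1 bindings and the traversal must backtrack twice before moving on
to root 2.
"""

from __future__ import annotations

import json
import random
from pathlib import Path
from xml.sax.saxutils import escape

from .backend import MockDataset, Record
from .errors import FixtureError
from .registry import (
    DatabaseDescriptor,
    FieldDescriptor,
    LinkDescriptor,
    Registry,
)

DB_NAME_POOL = [
    "pubmed", "gene", "protein", "nuccore", "taxonomy", "snp", "omim",
    "structure", "biosample", "sra", "cdd", "assembly",
]

# (code, label, may_be_asymmetric)
FIELD_POOL = [
    ("TITL", "Title"), ("AUTH", "Author"), ("JOUR", "Journal"),
    ("PDAT", "Publication Date"), ("LANG", "Language"), ("ABST", "Abstract"),
    ("ORGN", "Organism"), ("SYMB", "Symbol"), ("CHR", "Chromosome"),
    ("DESC", "Description"), ("ACCN", "Accession"), ("MESH", "MeSH Term"),
]

WORD_POOL = [
    "wilms", "tumor", "kidney", "carcinoma", "nephroblastoma", "renal",
    "pediatric", "gene", "expression", "mutation", "pathway", "signal",
    "protein", "sequence", "variant", "clinical", "trial", "therapy",
    "biomarker", "genome", "cell", "growth", "factor", "human", "murine",
]


def _rng_fanout(rng: random.Random, spec) -> int:
    if isinstance(spec, dict):
        values = list(spec)
        weights = [spec[v] for v in values]
        return rng.choices(values, weights=weights, k=1)[0]
    return rng.choice(list(spec))


def _validate_fanout(spec) -> None:
    try:
        items = list(spec.items()) if isinstance(spec, dict) else [(v, 1) for v in spec]
    except TypeError:
        raise FixtureError(f"invalid fan-out spec: {spec!r}") from None
    if not items:
        raise FixtureError("fan-out spec is empty")
    for v, w in items:
        if not isinstance(v, int) or v < 0 or w <= 0:
            raise FixtureError(f"invalid fan-out spec entry: {v!r}: {w!r}")


def generate_fixture(seed: int,
                     n_dbs: int = 3,
                     records_per_db: tuple[int, int] = (5, 30),
                     fanout=(0, 1, 2, 5),
                     asymmetric_field_fraction: float = 0.3) -> MockDataset:
    """Generate a deterministic mock dataset.

    ``fanout`` is either a sequence of per-source out-degrees (chosen
    uniformly) or a mapping degree -> weight.  ``asymmetric_field_fraction``
    is the expected share of fields that are filter-only or retrieve-only
    (split evenly between the two kinds).
    """
    if n_dbs < 1:
        raise FixtureError("n_dbs must be >= 1")
    _validate_fanout(fanout)
    if isinstance(records_per_db, int):
        records_per_db = (records_per_db, records_per_db)
    rng = random.Random(seed)

    db_names = [DB_NAME_POOL[i] if i < len(DB_NAME_POOL) else f"mockdb{i}"
                for i in range(n_dbs)]

    databases: dict[str, DatabaseDescriptor] = {}
    for i, name in enumerate(db_names):
        n_fields = rng.randint(4, 8)
        chosen = rng.sample(FIELD_POOL, n_fields)
        filterable_fields: list[FieldDescriptor] = []
        retrieve_only: list[FieldDescriptor] = []
        for code, label in chosen:
            roll = rng.random()
            if roll < asymmetric_field_fraction / 2:
                filterable_fields.append(FieldDescriptor(code, label, True, False))
            elif roll < asymmetric_field_fraction:
                retrieve_only.append(FieldDescriptor(code, code, False, True))
            else:
                filterable_fields.append(FieldDescriptor(code, label, True, True))
        # keep every database searchable and projectable
        if not filterable_fields:
            code, label = chosen[0]
            filterable_fields = [FieldDescriptor(code, label, True, True)]
            retrieve_only = [f for f in retrieve_only if f.name != code]
        if not any(f.retrievable for f in filterable_fields) and not retrieve_only:
            first = filterable_fields[0]
            filterable_fields[0] = FieldDescriptor(first.name, first.full_name,
                                                   True, True)
        databases[name] = DatabaseDescriptor(
            name=name,
            description=f"synthetic mock of the {name} database",
            fields=filterable_fields + retrieve_only,
            supports_efetch=rng.random() < 0.5,
        )

    # reciprocal links along the chain; occasional extra forward link
    links: list[LinkDescriptor] = []
    for a, b in zip(db_names, db_names[1:]):
        links.append(LinkDescriptor(f"{a}_{b}", a, b))
        links.append(LinkDescriptor(f"{b}_{a}", b, a))
    for a in db_names:
        for b in db_names:
            if a != b and abs(db_names.index(a) - db_names.index(b)) > 1:
                if rng.random() < 0.25:
                    links.append(LinkDescriptor(f"{a}_{b}", a, b))
    for link in links:
        databases[link.source_db].links.append(link)

    tables: dict[str, dict[str, Record]] = {}
    for i, name in enumerate(db_names):
        n_rec = rng.randint(*records_per_db)
        table: dict[str, Record] = {}
        for j in range(n_rec):
            uid = f"{i + 1}{j:05d}"
            values = {}
            for f in databases[name].fields:
                if rng.random() < 0.85:
                    k = rng.randint(1, 3)
                    values[f.name] = " ".join(rng.choice(WORD_POOL)
                                              for _ in range(k))
            table[uid] = Record(uid=uid, values=values)
        tables[name] = table

    link_tables: dict[str, dict[str, list[str]]] = {}
    for link in links:
        src_uids = list(tables[link.source_db])
        dst_uids = list(tables[link.target_db])
        lt: dict[str, list[str]] = {}
        for uid in src_uids:
            k = _rng_fanout(rng, fanout)
            if k and dst_uids:
                lt[uid] = rng.sample(dst_uids, min(k, len(dst_uids)))
        link_tables[link.name] = lt

    summary_fields = {
        name: [f.name for f in db.fields if f.retrievable]
        for name, db in databases.items()
    }

    registry = Registry(databases=databases,
                        generated_at=f"fixture-seed-{seed}")
    manifest = {
        "seed": seed,
        "n_dbs": n_dbs,
        "records_per_db": list(records_per_db),
        "fanout": (dict(fanout) if isinstance(fanout, dict)
                   else {str(v): 1 for v in fanout}),
        "asymmetric_field_fraction": asymmetric_field_fraction,
        "databases": {
            name: {
                "n_records": len(tables[name]),
                "fields": [f.name for f in databases[name].fields],
                "filter_only": [f.name for f in databases[name].fields
                                if f.filterable and not f.retrievable],
                "retrieve_only": [f.name for f in databases[name].fields
                                  if f.retrievable and not f.filterable],
                "links": [l.name for l in databases[name].links],
            }
            for name in db_names
        },
        "links": {
            link.name: {
                "source_db": link.source_db,
                "target_db": link.target_db,
                "n_edges": sum(len(v) for v in link_tables[link.name].values()),
            }
            for link in links
        },
    }
    return MockDataset(registry=registry, tables=tables,
                       link_tables=link_tables,
                       summary_fields=summary_fields, manifest=manifest)


# ---------------------------------------------------------------------------
# the worked-example topology


def worked_example_dataset(seed: int = 0,
                           n_roots: int = 20,
                           n_leaves: int = 557) -> MockDataset:
    """Three-level chain fixture: pubmed -> gene -> pubmed.

    The search term ``"wilms tumor"[TITL]`` matches exactly ``n_roots``
    articles; the first links to exactly one gene, which links back to
    ``n_leaves`` distinct articles.  Every later root links to one or two
    genes and every gene to between one and three articles, so the traversal
    always finds a live branch after backtracking out of the first one.
    """
    rng = random.Random(seed)

    pubmed = DatabaseDescriptor(
        name="pubmed",
        description="synthetic mock of the PubMed citation database",
        fields=[
            FieldDescriptor("TITL", "Title", True, True),
            FieldDescriptor("AUTH", "Author", True, True),
            FieldDescriptor("PDAT", "Publication Date", True, False),
            FieldDescriptor("LANG", "LANG", False, True),
        ],
        supports_efetch=True,
    )
    gene = DatabaseDescriptor(
        name="gene",
        description="synthetic mock of the Gene database",
        fields=[
            FieldDescriptor("SYMB", "Symbol", True, True),
            FieldDescriptor("ORGN", "Organism", True, True),
            FieldDescriptor("DESC", "DESC", False, True),
        ],
        supports_efetch=False,
    )
    links = [
        LinkDescriptor("pubmed_gene", "pubmed", "gene"),
        LinkDescriptor("gene_pubmed", "gene", "pubmed"),
    ]
    pubmed.links = [links[0]]
    gene.links = [links[1]]
    registry = Registry(databases={"pubmed": pubmed, "gene": gene},
                        generated_at=f"fixture-seed-{seed}")

    pubmed_table: dict[str, Record] = {}
    gene_table: dict[str, Record] = {}

    def article(uid: str, title: str) -> None:
        values = {"TITL": title,
                  "AUTH": " ".join(rng.sample(WORD_POOL, 2)),
                  "PDAT": f"20{rng.randint(0, 25):02d}"}
        if rng.random() < 0.8:
            values["LANG"] = rng.choice(["eng", "ger", "spa", "fre"])
        pubmed_table[uid] = Record(uid=uid, values=values)

    roots = [f"1{i:05d}" for i in range(n_roots)]
    for i, uid in enumerate(roots):
        article(uid, f"wilms tumor study {i}: "
                     + " ".join(rng.sample(WORD_POOL[2:], 2)))

    per_root_genes = [1] + [rng.randint(1, 2) for _ in roots[1:]]
    n_genes = sum(per_root_genes)
    genes = [f"2{i:05d}" for i in range(n_genes)]
    for i, uid in enumerate(genes):
        gene_table[uid] = Record(uid=uid, values={
            "SYMB": f"WT{i + 1}",
            "ORGN": rng.choice(["homo sapiens", "mus musculus"]),
            "DESC": " ".join(rng.sample(WORD_POOL[2:], 3)),
        })

    pubmed_gene: dict[str, list[str]] = {}
    gene_pubmed: dict[str, list[str]] = {}
    cursor = 0
    for uid, k in zip(roots, per_root_genes):
        pubmed_gene[uid] = genes[cursor:cursor + k]
        cursor += k

    leaf_counter = 0

    def leaves_for(gene_uid: str, count: int) -> list[str]:
        nonlocal leaf_counter
        out = []
        for _ in range(count):
            uid = f"3{leaf_counter:05d}"
            leaf_counter += 1
            article(uid, f"expression of {gene_table[gene_uid].values['SYMB']} in "
                         + " ".join(rng.sample(WORD_POOL[2:], 2)))
            out.append(uid)
        return out

    gene_pubmed[genes[0]] = leaves_for(genes[0], n_leaves)
    for g in genes[1:]:
        gene_pubmed[g] = leaves_for(g, rng.randint(1, 3))

    summary_fields = {"pubmed": ["TITL", "AUTH", "LANG"],
                      "gene": ["SYMB", "ORGN", "DESC"]}
    manifest = {
        "seed": seed,
        "topology": "worked-example",
        "n_roots": n_roots,
        "n_leaves_root1": n_leaves,
        "n_genes": n_genes,
        "root_term": '"wilms tumor"[TITL]',
        "databases": {"pubmed": {"n_records": len(pubmed_table)},
                      "gene": {"n_records": len(gene_table)}},
    }
    return MockDataset(
        registry=registry,
        tables={"pubmed": pubmed_table, "gene": gene_table},
        link_tables={"pubmed_gene": pubmed_gene, "gene_pubmed": gene_pubmed},
        summary_fields=summary_fields,
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# EInfo-dialect rendering (so the metadata pipeline can run offline)


def render_einfo_master(registry: Registry) -> str:
    names = "\n".join(f"    <DbName>{escape(n)}</DbName>"
                      for n in registry.databases)
    return ("<?xml version=\"1.0\"?>\n<eInfoResult>\n  <DbList>\n"
            f"{names}\n  </DbList>\n</eInfoResult>\n")


def render_einfo_db(db: DatabaseDescriptor) -> str:
    """Per-database EInfo document: declares the *filterable* fields and the
    outgoing links (retrieve-only fields are invisible here, as on the live
    service — they only surface in the result evidence)."""
    fields = "\n".join(
        "      <Field>\n"
        f"        <Name>{escape(f.name)}</Name>\n"
        f"        <FullName>{escape(f.full_name)}</FullName>\n"
        "      </Field>"
        for f in db.fields if f.filterable
    )
    links = "\n".join(
        "      <Link>\n"
        f"        <Name>{escape(l.name)}</Name>\n"
        f"        <DbTo>{escape(l.target_db)}</DbTo>\n"
        "      </Link>"
        for l in db.links
    )
    return (
        "<?xml version=\"1.0\"?>\n<eInfoResult>\n  <DbInfo>\n"
        f"    <DbName>{escape(db.name)}</DbName>\n"
        f"    <Description>{escape(db.description)}</Description>\n"
        f"    <FieldList>\n{fields}\n    </FieldList>\n"
        f"    <LinkList>\n{links}\n    </LinkList>\n"
        "  </DbInfo>\n</eInfoResult>\n"
    )


def render_evidence(db: DatabaseDescriptor,
                    sample_record: Record | None = None) -> str:
    """Retrievable-field evidence: a result DTD for eFetch-capable databases,
    otherwise a sample eSummary result document."""
    codes = [f.name for f in db.fields if f.retrievable]
    if db.supports_efetch:
        children = ", ".join(codes) if codes else "EMPTY"
        decls = "\n".join(f"<!ELEMENT {c} (#PCDATA)>" for c in codes)
        root = f"<!ELEMENT {db.name.capitalize()}Record ({children})>"
        return f"{root}\n{decls}\n"
    items = "\n".join(
        f'    <Item Name="{escape(c)}" Type="String">'
        f"{escape((sample_record.values.get(c, 'sample') if sample_record else 'sample'))}"
        "</Item>"
        for c in codes
    )
    uid = sample_record.uid if sample_record else "000001"
    return ("<?xml version=\"1.0\"?>\n<eSummaryResult>\n  <DocSum>\n"
            f"    <Id>{escape(uid)}</Id>\n{items}\n  </DocSum>\n"
            "</eSummaryResult>\n")


# ---------------------------------------------------------------------------
# fixture directory I/O


def write_fixture_dir(dataset: MockDataset, path: str | Path) -> None:
    """Write a dataset as a directory of JSON tables plus EInfo-dialect
    metadata documents and the manifest."""
    root = Path(path)
    (root / "tables").mkdir(parents=True, exist_ok=True)
    (root / "links").mkdir(exist_ok=True)
    (root / "einfo").mkdir(exist_ok=True)
    (root / "evidence").mkdir(exist_ok=True)

    dataset.registry.save(root / "registry.json")
    (root / "manifest.json").write_text(json.dumps(dataset.manifest, indent=2))
    (root / "summary_fields.json").write_text(
        json.dumps(dataset.summary_fields, indent=2))
    for db, table in dataset.tables.items():
        doc = {uid: rec.values for uid, rec in table.items()}
        (root / "tables" / f"{db}.json").write_text(json.dumps(doc, indent=2))
    for link, lt in dataset.link_tables.items():
        (root / "links" / f"{link}.json").write_text(json.dumps(lt, indent=2))

    (root / "einfo" / "master.xml").write_text(
        render_einfo_master(dataset.registry))
    for db_name, db in dataset.registry.databases.items():
        (root / "einfo" / f"{db_name}.xml").write_text(render_einfo_db(db))
        sample = next(iter(dataset.tables.get(db_name, {}).values()), None)
        ext = "dtd" if db.supports_efetch else "xml"
        (root / "evidence" / f"{db_name}.{ext}").write_text(
            render_evidence(db, sample))


def load_fixture_dir(path: str | Path) -> MockDataset:
    root = Path(path)
    try:
        registry = Registry.load(root / "registry.json")
        manifest = json.loads((root / "manifest.json").read_text())
        summary_fields = json.loads((root / "summary_fields.json").read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise FixtureError(f"corrupt or missing fixture directory {root}: {exc}") from exc
    tables = {}
    for f in sorted((root / "tables").glob("*.json")):
        doc = json.loads(f.read_text())
        tables[f.stem] = {uid: Record(uid=uid, values=values)
                          for uid, values in doc.items()}
    link_tables = {}
    for f in sorted((root / "links").glob("*.json")):
        link_tables[f.stem] = json.loads(f.read_text())
    return MockDataset(registry=registry, tables=tables,
                       link_tables=link_tables,
                       summary_fields=summary_fields, manifest=manifest)
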