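import re

import pytest

from entrez_sparql import (
    DatabaseDescriptor,
    FieldDescriptor,
    build_registry,
    classify_retrievable,
    generate_fixture,
    parse_einfo_db,
    parse_einfo_master,
)
from entrez_sparql.errors import (
    ClassificationError,
    MetadataParseError,
    RegistryError,
)
from entrez_sparql.fixtures import (
    render_einfo_db,
    render_einfo_master,
    render_evidence,
)

MASTER = """<?xml version="1.0"?>
<eInfoResult><DbList>
  <DbName>PubMed</DbName>
  <DbName>gene</DbName>
  <DbName>pubmed</DbName>
</DbList></eInfoResult>
"""

PUBMED_EINFO = """<?xml version="1.0"?>
<eInfoResult><DbInfo>
  <DbName>pubmed</DbName>
  <Description>Citations database</Description>
  <FieldList>
    <Field><Name>TITL</Name><FullName>Title</FullName></Field>
    <Field><Name>PDAT</Name><FullName>Publication Date</FullName></Field>
    <Field><Name></Name><FullName>broken</FullName></Field>
  </FieldList>
  <LinkList>
    <Link><Name>pubmed_gene</Name><DbTo>gene</DbTo></Link>
    <Link><Name>pubmed_nowhere</Name><DbTo>nowhere</DbTo></Link>
  </LinkList>
</DbInfo></eInfoResult>
"""

GENE_EINFO = """<?xml version="1.0"?>
<eInfoResult><DbInfo>
  <DbName>gene</DbName>
  <FieldList>
    <Field><Name>SYMB</Name><FullName>Symbol</FullName></Field>
  </FieldList>
  <LinkList>
    <Link><Name>gene_pubmed</Name><DbTo>pubmed</DbTo></Link>
  </LinkList>
</DbInfo></eInfoResult>
"""

PUBMED_DTD = """<!ELEMENT PubmedRecord (TITL, LANG?)>
<!ELEMENT TITL (#PCDATA)>
<!ELEMENT LANG (#PCDATA)>
"""

GENE_SAMPLE = """<?xml version="1.0"?>
<eSummaryResult><DocSum>
  <Id>42</Id>
  <Item Name="SYMB" Type="String">WT1</Item>
</DocSum></eSummaryResult>
"""


class TestParseMaster:
    def test_lowercases_and_dedupes_in_order(self):
        assert parse_einfo_master(MASTER) == ["pubmed", "gene"]

    def test_empty_list_is_empty_not_error(self):
        assert parse_einfo_master("<eInfoResult><DbList/></eInfoResult>") == []

    def test_malformed_xml_names_position(self):
        with pytest.raises(MetadataParseError, match=r"line \d+"):
            parse_einfo_master("<eInfoResult><DbList>")

    def test_generated_master_matches_text_scan(self):
        # oracle: count DbName elements in the rendered document directly
        dataset = generate_fixture(11, n_dbs=5)
        doc = render_einfo_master(dataset.registry)
        scanned = re.findall(r"<DbName>([^<]+)</DbName>", doc)
        assert parse_einfo_master(doc) == scanned
        assert len(scanned) == 5


class TestParseDb:
    def test_fields_start_filterable_only(self):
        desc = parse_einfo_db(PUBMED_EINFO)
        assert desc.name == "pubmed"
        assert desc.description == "Citations database"
        assert [f.name for f in desc.fields] == ["TITL", "PDAT"]
        assert all(f.filterable and not f.retrievable for f in desc.fields)

    def test_links_carry_target(self):
        desc = parse_einfo_db(PUBMED_EINFO)
        assert [(l.name, l.source_db, l.target_db) for l in desc.links] == [
            ("pubmed_gene", "pubmed", "gene"),
            ("pubmed_nowhere", "pubmed", "nowhere"),
        ]

    def test_zero_links_gives_empty_list(self):
        doc = GENE_EINFO.replace(
            "<LinkList>\n    <Link><Name>gene_pubmed</Name><DbTo>pubmed</DbTo></Link>\n  </LinkList>",
            "<LinkList/>")
        assert parse_einfo_db(doc).links == []

    def test_missing_db_name_is_parse_error(self):
        with pytest.raises(MetadataParseError, match="DbName"):
            parse_einfo_db("<eInfoResult><DbInfo><FieldList/></DbInfo></eInfoResult>")

    def test_generated_einfo_matches_manifest(self):
        dataset = generate_fixture(5, n_dbs=2)
        name = dataset.registry.db_names()[0]
        db = dataset.registry[name]
        desc = parse_einfo_db(render_einfo_db(db))
        declared_filterable = [f.name for f in db.fields if f.filterable]
        assert [f.name for f in desc.fields] == declared_filterable
        assert [l.name for l in desc.links] == \
            dataset.manifest["databases"][name]["links"]


class TestClassifyRetrievable:
    def test_filter_only_field_survives_unretrievable(self):
        desc = classify_retrievable(parse_einfo_db(PUBMED_EINFO), PUBMED_DTD)
        pdat = desc.field_map()["PDAT"]
        assert pdat.filterable and not pdat.retrievable

    def test_evidence_only_field_added_retrieve_only(self):
        desc = classify_retrievable(parse_einfo_db(PUBMED_EINFO), PUBMED_DTD)
        lang = desc.field_map()["LANG"]
        assert lang.retrievable and not lang.filterable
        assert lang.full_name == "LANG"

    def test_symmetric_evidence_marks_everything(self):
        dtd = "<!ELEMENT Rec (TITL, PDAT)>\n<!ELEMENT TITL (#PCDATA)>\n<!ELEMENT PDAT (#PCDATA)>\n"
        desc = classify_retrievable(parse_einfo_db(PUBMED_EINFO), dtd)
        assert all(f.filterable and f.retrievable for f in desc.fields)

    def test_evidence_kind_sets_efetch_support(self):
        dtd_desc = classify_retrievable(parse_einfo_db(PUBMED_EINFO), PUBMED_DTD)
        doc_desc = classify_retrievable(parse_einfo_db(GENE_EINFO), GENE_SAMPLE)
        assert dtd_desc.supports_efetch and not doc_desc.supports_efetch
        assert doc_desc.field_map()["SYMB"].retrievable

    def test_unparseable_evidence_raises(self):
        with pytest.raises(ClassificationError):
            classify_retrievable(parse_einfo_db(GENE_EINFO), "<DocSum><broken")

    def test_empty_evidence_warns_but_returns(self, caplog):
        desc = classify_retrievable(parse_einfo_db(GENE_EINFO),
                                    "<eSummaryResult></eSummaryResult>")
        assert desc.retrievable_fields() == []


class TestBuildRegistry:
    def test_two_dbs_reciprocal_links(self):
        reg = build_registry(MASTER,
                             {"pubmed": PUBMED_EINFO, "gene": GENE_EINFO},
                             {"pubmed": PUBMED_DTD, "gene": GENE_SAMPLE})
        assert reg.db_names() == ["pubmed", "gene"]
        names = {l.name for l in reg.links()}
        assert names == {"pubmed_gene", "gene_pubmed"}

    def test_dangling_link_pruned(self):
        reg = build_registry(MASTER, {"pubmed": PUBMED_EINFO, "gene": GENE_EINFO})
        assert "pubmed_nowhere" not in {l.name for l in reg.links()}

    def test_empty_master_is_fatal(self):
        with pytest.raises(RegistryError):
            build_registry("<eInfoResult><DbList/></eInfoResult>", {})

    def test_missing_einfo_skips_db_and_incident_links(self):
        dataset = generate_fixture(21, n_dbs=5)
        reg = dataset.registry
        master = render_einfo_master(reg)
        per_db = {n: render_einfo_db(reg[n]) for n in reg.db_names()}
        evidence = {n: render_evidence(reg[n]) for n in reg.db_names()}
        removed = reg.db_names()[2]
        del per_db[removed]
        rebuilt = build_registry(master, per_db, evidence)
        assert removed not in rebuilt
        assert len(rebuilt.databases) == 4
        # oracle: manifest minus the removed db and its incident links
        expected_links = {l.name for l in reg.links()
                          if removed not in (l.source_db, l.target_db)}
        assert {l.name for l in rebuilt.links()} == expected_links

    def test_idempotent_and_closed(self):
        dataset = generate_fixture(8, n_dbs=3)
        reg = dataset.registry
        args = (render_einfo_master(reg),
                {n: render_einfo_db(reg[n]) for n in reg.db_names()},
                {n: render_evidence(reg[n]) for n in reg.db_names()})
        r1, r2 = build_registry(*args), build_registry(*args)
        assert r1 == r2  # generated_at excluded from equality
        assert all(l.target_db in r1 for l in r1.links())

    def test_json_cache_round_trip(self, tmp_path):
        reg = generate_fixture(9, n_dbs=3).registry
        reg.save(tmp_path / "registry.json")
        from entrez_sparql import Registry
        assert Registry.load(tmp_path / "registry.json") == reg


def test_field_invariant_neither_flag_dropped(caplog):
    # a field that is neither filterable nor retrievable is useless
    import logging
    master = "<eInfoResult><DbList><DbName>pubmed</DbName></DbList></eInfoResult>"
    with caplog.at_level(logging.WARNING):
        reg = build_registry(master, {"pubmed": PUBMED_EINFO},
                             {"pubmed": "<!ELEMENT Rec EMPTY>\n"})
    # evidence names zero retrievable leaf fields -> EInfo fields survive as
    # filter-only (still useful); nothing is dropped here
    assert set(reg["pubmed"].field_map()) == {"TITL", "PDAT", "REC"}
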