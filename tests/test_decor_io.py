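"""XML dialect and YAML report I/O: parsing, writing, round-trips."""

import logging

import pytest

from cdacover import decor_io, fixtures
from cdacover.analyzer import CoverageReport, CoverageRow, UseCaseRow
from cdacover.associations import AssociationDocument, TemplateAssociation
from cdacover.model import Code, ContentKind, FixedBinding, ValueSetBinding


CONCEPTS_XML = """<?xml version="1.0" encoding="UTF-8"?>
<decor project="p1">
  <dataset id="ds-f" name="Feasibility" useCase="feasibility">
    <concept id="g1" type="group"><name>Laboratory findings</name>
      <concept id="c1" type="item" dataType="Quantity">
        <name>Albumin</name>
        <code code="C1" codeSystem="FAKE-UMLS"/>
        <code code="S1" codeSystem="FAKE-SNOMED"/>
      </concept>
    </concept>
  </dataset>
  <dataset id="ds-empty" name="Empty" useCase="execution"/>
</decor>
"""

TEMPLATES_XML = """<?xml version="1.0" encoding="UTF-8"?>
<decor project="bbr1">
  <template id="t-lab" effectiveDate="2021-01-01" name="Laboratory Observation">
    <element id="e-code" name="hl7:code" contentKind="coded">
      <vocabulary valueSet="vs-lab"/>
    </element>
    <element id="e-value" name="hl7:value" contentKind="quantity"/>
  </template>
  <template id="t-text" effectiveDate="2021-01-01" name="Lifestyle - uncoded">
    <element id="e-text" name="hl7:text" contentKind="narrative_text"/>
  </template>
  <valueSet id="vs-lab" effectiveDate="2019-04-01">
    <conceptList><concept code="L-1" codeSystem="FAKE-LOINC"/></conceptList>
  </valueSet>
  <valueSet id="vs-lab" effectiveDate="2021-06-01">
    <conceptList><concept code="L-1" codeSystem="FAKE-LOINC"/></conceptList>
  </valueSet>
  <documentType id="dt1" status="Normative">
    <templateRef ref="t-lab"/>
  </documentType>
  <documentType id="dt2" status="Draft">
    <templateRef ref="t-text"/>
  </documentType>
</decor>
"""


class TestConceptRepositoryParsing:
    def test_datasets_concepts_codes_populated(self):
        repo = decor_io.parse_concept_repository(CONCEPTS_XML)
        assert repo.project_id == "p1"
        ds = repo.dataset("ds-f")
        c = ds.concept("c1")
        assert c.name == "Albumin"
        assert c.group_path == ("Laboratory findings",)
        assert len(c.codes) == 2

    def test_empty_dataset_warns_and_parses(self, caplog):
        with caplog.at_level(logging.WARNING):
            repo = decor_io.parse_concept_repository(CONCEPTS_XML)
        assert repo.dataset("ds-empty").concepts == []
        assert any("ds-empty" in r.message for r in caplog.records)

    def test_elga_preset_counts_survive_round_trip(self, elga_bundle):
        xml = decor_io.write_concept_repository(elga_bundle.concepts)
        repo = decor_io.parse_concept_repository(xml)
        sizes = {d.id: len(d.concepts) for d in repo.use_case_datasets()}
        assert sizes == {"ds-feasibility": 75, "ds-recruitment": 149, "ds-execution": 133}

    def test_malformed_xml_reports_parse_error(self):
        with pytest.raises(decor_io.DecorParseError, match="line"):
            decor_io.parse_concept_repository("<decor project='p'><dataset</decor>")

    def test_missing_mandatory_attribute_names_element(self):
        xml = '<decor project="p"><dataset name="x" useCase="feasibility"/></decor>'
        with pytest.raises(decor_io.DecorSchemaError, match="dataset.*'id'"):
            decor_io.parse_concept_repository(xml)


class TestTemplateRepositoryParsing:
    def test_generic_lab_template(self):
        repo = decor_io.parse_template_repository(TEMPLATES_XML)
        t = repo.template("t-lab", "2021-01-01")
        assert len(t.elements) == 2
        assert t.elements[0].binding == ValueSetBinding("vs-lab")
        assert t.elements[1].content_kind is ContentKind.QUANTITY

    def test_narrative_only_template(self):
        repo = decor_io.parse_template_repository(TEMPLATES_XML)
        t = repo.template("t-text", "2021-01-01")
        assert t.elements[0].content_kind is ContentKind.NARRATIVE_TEXT
        assert t.elements[0].binding is None

    def test_value_set_versions_kept_separately(self):
        repo = decor_io.parse_template_repository(TEMPLATES_XML)
        versions = repo.valueset_versions("vs-lab")
        assert [v.effective_date for v in versions] == ["2019-04-01", "2021-06-01"]

    def test_normative_flag_from_document_type_status(self):
        repo = decor_io.parse_template_repository(TEMPLATES_XML)
        assert repo.template("t-lab", "2021-01-01").normative
        assert not repo.template("t-text", "2021-01-01").normative

    def test_dangling_valueset_binding_rejected(self):
        xml = TEMPLATES_XML.replace('valueSet="vs-lab"/>', 'valueSet="vs-gone"/>', 1)
        with pytest.raises(Exception, match="vs-gone"):
            decor_io.parse_template_repository(xml)


class TestAssociations:
    def _doc(self):
        return AssociationDocument(
            "m1",
            frozenset(
                {
                    TemplateAssociation(
                        "c1",
                        "t-lab",
                        "2021-01-01",
                        ("e-code", "e-value"),
                        qualifier=Code("FAKE-LOINC", "L-1"),
                        provenance="automatic",
                    ),
                    TemplateAssociation("c2", "t-text", "2021-01-01", ("e-text",)),
                }
            ),
        )

    def test_round_trip_preserves_association_set(self):
        doc = self._doc()
        parsed = decor_io.parse_associations(decor_io.write_associations(doc))
        assert parsed.associations == doc.associations
        assert parsed.project_id == "m1"

    def test_qualifier_survives_round_trip(self):
        doc = self._doc()
        parsed = decor_io.parse_associations(decor_io.write_associations(doc))
        (paired,) = [a for a in parsed.associations if len(a.element_ids) == 2]
        assert paired.qualifier == Code("FAKE-LOINC", "L-1")
        assert paired.provenance == "automatic"

    def test_empty_document_round_trips(self):
        doc = AssociationDocument("empty", frozenset())
        parsed = decor_io.parse_associations(decor_io.write_associations(doc))
        assert parsed.associations == frozenset()

    def test_duplicate_association_deduplicated_with_warning(self, caplog):
        xml = """<decor project="m">
          <templateAssociation concept="c1" template="t" effectiveDate="d"><element id="e"/></templateAssociation>
          <templateAssociation concept="c1" template="t" effectiveDate="d"><element id="e"/></templateAssociation>
        </decor>"""
        with caplog.at_level(logging.WARNING):
            doc = decor_io.parse_associations(xml)
        assert len(doc.associations) == 1
        assert any("Duplicate" in r.message for r in caplog.records)


class TestReportYaml:
    def _report(self):
        groups = [CoverageRow("Laboratory findings", 41, 41, 41)]
        row = UseCaseRow("Feasibility checking", 41, 41, 41, groups=groups)
        return CoverageReport([row], CoverageRow("Overall", 41, 41, 41))

    def test_round_trip_equals_report_mapping(self):
        rep = self._report()
        assert decor_io.parse_report_yaml(decor_io.write_report_yaml(rep)) == rep.to_mapping()

    def test_overall_block_carries_counts_and_percentages(self, elga_results):
        report, _, _ = elga_results
        data = decor_io.parse_report_yaml(decor_io.write_report_yaml(report))
        assert data["overall"] == {
            "label": "Overall",
            "concepts": 357,
            "mapped": 315,
            "mapped_pct": 88,
            "structured": 275,
            "structured_pct": 77,
        }

    def test_byte_identical_across_runs(self, elga_results):
        report, _, _ = elga_results
        assert decor_io.write_report_yaml(report) == decor_io.write_report_yaml(report)

    def test_report_honours_shipped_schema_contract(self, elga_results):
        import json
        import pathlib

        import cdacover

        schema = json.loads(
            (pathlib.Path(cdacover.__file__).parent / "schemas" / "coverage_report.schema.json").read_text()
        )
        required = set(schema["$defs"]["row"]["required"])
        report, _, _ = elga_results
        data = decor_io.parse_report_yaml(decor_io.write_report_yaml(report))
        rows = [data["overall"]] + data["use_cases"] + [
            g for uc in data["use_cases"] for g in uc["groups"]
        ]
        for row in rows:
            assert required <= set(row)
            assert isinstance(row["mapped_pct"], int) and 0 <= row["mapped_pct"] <= 100


@pytest.mark.parametrize("seed", range(6))
def test_randomized_documents_round_trip(seed):
    """Write-parse identity (as sets of sibling records) for all three
    document kinds on generator-produced documents."""
    bundle = fixtures.generate(
        fixtures.FixtureSpec(seed=seed, n_feasibility=12, n_recruitment=9,
                             n_execution=10, n_shared=3)
    )
    repo2 = decor_io.parse_concept_repository(
        decor_io.write_concept_repository(bundle.concepts)
    )
    for d1, d2 in zip(bundle.concepts.datasets, repo2.datasets):
        assert (d1.id, d1.use_case) == (d2.id, d2.use_case)
        assert set(d1.concepts) == set(d2.concepts)
    trepo2 = decor_io.parse_template_repository(
        decor_io.write_template_repository(bundle.templates)
    )
    assert set(trepo2.templates) == set(bundle.templates.templates)
    assert set(trepo2.value_sets) == set(bundle.templates.value_sets)
    doc2 = decor_io.parse_associations(
        decor_io.write_associations(bundle.manual_associations)
    )
    assert doc2.associations == bundle.manual_associations.associations
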