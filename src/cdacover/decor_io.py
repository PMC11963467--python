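"""Read/write the DECOR-style XML dialect and the YAML coverage report.

The dialect is a documented *subset* of the ART-DECOR exchange format:
``dataset``/``concept`` elements for concept repositories, ``template``/
``valueSet``/``documentType`` elements for building-block repositories, and
``templateAssociation`` records for mapping project files — each using the
``id``, ``effectiveDate``, ``code`` and ``codeSystem`` attributes the real
exports use.  Full ART-DECOR compatibility is not promised, but files
restricted to these elements parse.  Encoding is fixed to UTF-8 and effective
dates are ISO-8601 strings compared lexicographically as version keys.

Document grammar (informal)::

    <decor project="PID">
      <dataset id name useCase>
        <concept id type="group"><name>..</name> <concept .../> </concept>
        <concept id type="item" dataType>
          <name>..</name> <desc>..</desc>
          <code code codeSystem [displayName]/>
          <inherit ref dataset/>          <!-- instead of dataType/code -->
        </concept>
      </dataset>
      <template id effectiveDate name>
        <element id name contentKind>
          <code code codeSystem/> | <vocabulary valueSet [effectiveDate]/>
        </element>
      </template>
      <valueSet id effectiveDate [name]>
        <conceptList><concept code codeSystem [displayName]/></conceptList>
      </valueSet>
      <documentType id status><templateRef ref [effectiveDate]/></documentType>
      <templateAssociation concept template effectiveDate provenance
                           [qualifierCode qualifierCodeSystem]>
        <element id/>
      </templateAssociation>
    </decor>
"""

from __future__ import annotations

import logging
import urllib.request
from typing import Optional, Union

import yaml
from lxml import etree

from .associations import AssociationDocument, TemplateAssociation
from .model import (
    Code,
    Concept,
    ConceptDataType,
    ConceptRepository,
    ContentKind,
    Dataset,
    FixedBinding,
    Inherited,
    Template,
    TemplateElement,
    TemplateRepository,
    UseCase,
    ValueSet,
    ValueSetBinding,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DecorParseError",
    "DecorSchemaError",
    "parse_concept_repository",
    "write_concept_repository",
    "parse_template_repository",
    "write_template_repository",
    "parse_associations",
    "write_associations",
    "write_report_yaml",
    "parse_report_yaml",
    "fetch_project",
]


class DecorParseError(ValueError):
    """Malformed XML (carries the libxml line number in the message)."""


class DecorSchemaError(ValueError):
    """Well-formed XML that violates the documented dialect."""


def _root(xml_text: Union[str, bytes]) -> etree._Element:
    if isinstance(xml_text, str):
        xml_text = xml_text.encode("utf-8")
    try:
        return etree.fromstring(xml_text)
    except etree.XMLSyntaxError as exc:
        raise DecorParseError(f"Malformed XML: {exc}") from exc


def _require(el: etree._Element, attr: str) -> str:
    value = el.get(attr)
    if value is None:
        raise DecorSchemaError(
            f"<{el.tag}> (line {el.sourceline}) is missing mandatory "
            f"attribute {attr!r}"
        )
    return value


def _parse_code(el: etree._Element) -> Code:
    return Code(
        system=_require(el, "codeSystem"),
        code=_require(el, "code"),
        display=el.get("displayName"),
    )


def _code_attrs(code: Code) -> dict[str, str]:
    attrs = {"code": code.code, "codeSystem": code.system}
    if code.display:
        attrs["displayName"] = code.display
    return attrs


# ---------------------------------------------------------------------------
# concept repository
# ---------------------------------------------------------------------------


def _parse_concept_item(el: etree._Element, group_path: tuple[str, ...]) -> Concept:
    cid = _require(el, "id")
    name_el = el.find("name")
    desc_el = el.find("desc")
    inherit_el = el.find("inherit")
    origin: Optional[Inherited] = None
    data_type: Optional[ConceptDataType] = None
    if inherit_el is not None:
        origin = Inherited(
            source_dataset=_require(inherit_el, "dataset"),
            source_concept=_require(inherit_el, "ref"),
        )
    dt_attr = el.get("dataType")
    if dt_attr is not None:
        try:
            data_type = ConceptDataType(dt_attr)
        except ValueError:
            raise DecorSchemaError(
                f"Concept {cid!r} (line {el.sourceline}): unknown dataType "
                f"{dt_attr!r}"
            ) from None
    elif origin is None:
        raise DecorSchemaError(
            f"Concept {cid!r} (line {el.sourceline}) has neither dataType "
            "nor an <inherit> reference"
        )
    codes = frozenset(_parse_code(c) for c in el.findall("code"))
    return Concept(
        id=cid,
        name=name_el.text.strip() if name_el is not None and name_el.text else "",
        data_type=data_type,
        group_path=group_path if group_path else ("Ungrouped",),
        description=desc_el.text.strip() if desc_el is not None and desc_el.text else "",
        codes=codes,
        origin=origin,
    )


def _walk_concepts(
    parent: etree._Element, group_path: tuple[str, ...], out: list[Concept]
) -> None:
    for el in parent.findall("concept"):
        kind = el.get("type", "item")
        if kind == "group":
            name_el = el.find("name")
            label = (
                name_el.text.strip()
                if name_el is not None and name_el.text
                else _require(el, "id")
            )
            _walk_concepts(el, group_path + (label,), out)
        else:
            if not group_path:
                logger.warning(
                    "Concept %r sits outside any group; placed under 'Ungrouped'",
                    el.get("id"),
                )
            out.append(_parse_concept_item(el, group_path))


def parse_concept_repository(xml_text: Union[str, bytes]) -> ConceptRepository:
    """Parse a concept-repository project file.

    Returns the repository *as written* — inherited concepts are stubs until
    :func:`cdacover.model.resolve_inheritance` materializes them.
    """
    root = _root(xml_text)
    project_id = _require(root, "project")
    datasets: list[Dataset] = []
    for ds_el in root.findall("dataset"):
        ds_id = _require(ds_el, "id")
        use_case_attr = _require(ds_el, "useCase")
        try:
            use_case = UseCase(use_case_attr)
        except ValueError:
            raise DecorSchemaError(
                f"Dataset {ds_id!r}: unknown useCase {use_case_attr!r}"
            ) from None
        concepts: list[Concept] = []
        _walk_concepts(ds_el, (), concepts)
        if not concepts:
            logger.warning("Dataset %r contains no concepts", ds_id)
        datasets.append(
            Dataset(ds_id, ds_el.get("name", ds_id), use_case, concepts)
        )
        logger.info("Parsed dataset %s: %d concepts", ds_id, len(concepts))
    repo = ConceptRepository(project_id, datasets)
    logger.info(
        "Parsed concept repository %s: %d datasets, %d use-case concept instances",
        project_id,
        len(datasets),
        repo.n_concept_instances(),
    )
    return repo


def write_concept_repository(repo: ConceptRepository) -> str:
    root = etree.Element("decor", project=repo.project_id)
    for ds in repo.datasets:
        ds_el = etree.SubElement(
            root, "dataset", id=ds.id, name=ds.name, useCase=ds.use_case.value
        )
        # regroup concepts under their group path, preserving first-appearance order
        group_els: dict[tuple[str, ...], etree._Element] = {}

        def group_el(path: tuple[str, ...]) -> etree._Element:
            if not path:
                return ds_el
            if path not in group_els:
                parent = group_el(path[:-1])
                g = etree.SubElement(
                    parent, "concept", id=f"{ds.id}-g-{len(group_els)}", type="group"
                )
                etree.SubElement(g, "name").text = path[-1]
                group_els[path] = g
            return group_els[path]

        for c in ds.concepts:
            parent = group_el(c.group_path)
            attrs = {"id": c.id, "type": "item"}
            if c.data_type is not None:
                attrs["dataType"] = c.data_type.value
            c_el = etree.SubElement(parent, "concept", **attrs)
            if c.name:
                etree.SubElement(c_el, "name").text = c.name
            if c.description:
                etree.SubElement(c_el, "desc").text = c.description
            if c.origin is not None:
                etree.SubElement(
                    c_el,
                    "inherit",
                    ref=c.origin.source_concept,
                    dataset=c.origin.source_dataset,
                )
            for code in sorted(c.codes):
                etree.SubElement(c_el, "code", **_code_attrs(code))
    return etree.tostring(
        root, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    ).decode("utf-8")


# ---------------------------------------------------------------------------
# template repository
# ---------------------------------------------------------------------------

_KIND_ATTR = {k.value: k for k in ContentKind}


def parse_template_repository(xml_text: Union[str, bytes]) -> TemplateRepository:
    """Parse a building-block repository file.

    The normative flag of each template is derived from the file's document
    types: a template is normative iff some ``documentType`` of status
    "Normative" references it (an undated ``templateRef`` covers all
    versions).
    """
    root = _root(xml_text)
    repo_id = _require(root, "project")

    value_sets: list[ValueSet] = []
    for vs_el in root.findall("valueSet"):
        codes = frozenset(
            _parse_code(c)
            for cl in vs_el.findall("conceptList")
            for c in cl.findall("concept")
        )
        if not codes:
            raise DecorSchemaError(
                f"Value set {vs_el.get('id')!r} (line {vs_el.sourceline}) has no codes"
            )
        value_sets.append(
            ValueSet(
                valueset_id=_require(vs_el, "id"),
                effective_date=_require(vs_el, "effectiveDate"),
                codes=codes,
                name=vs_el.get("name", ""),
            )
        )

    # normative references: (template_id, effective_date or None)
    normative_refs: set[tuple[str, Optional[str]]] = set()
    for dt_el in root.findall("documentType"):
        if dt_el.get("status") != "Normative":
            continue
        for ref_el in dt_el.findall("templateRef"):
            normative_refs.add((_require(ref_el, "ref"), ref_el.get("effectiveDate")))

    templates: list[Template] = []
    for t_el in root.findall("template"):
        t_id = _require(t_el, "id")
        t_date = _require(t_el, "effectiveDate")
        elements: list[TemplateElement] = []
        for e_el in t_el.findall("element"):
            kind_attr = _require(e_el, "contentKind")
            if kind_attr not in _KIND_ATTR:
                raise DecorSchemaError(
                    f"Element {e_el.get('id')!r} (line {e_el.sourceline}): "
                    f"unknown contentKind {kind_attr!r}"
                )
            binding = None
            code_el = e_el.find("code")
            vocab_el = e_el.find("vocabulary")
            if code_el is not None:
                binding = FixedBinding(_parse_code(code_el))
            elif vocab_el is not None:
                binding = ValueSetBinding(
                    valueset_id=_require(vocab_el, "valueSet"),
                    effective_date=vocab_el.get("effectiveDate"),
                )
            elements.append(
                TemplateElement(
                    element_id=_require(e_el, "id"),
                    path=_require(e_el, "name"),
                    content_kind=_KIND_ATTR[kind_attr],
                    binding=binding,
                )
            )
        normative = (t_id, None) in normative_refs or (t_id, t_date) in normative_refs
        templates.append(
            Template(
                template_id=t_id,
                effective_date=t_date,
                name=t_el.get("name", t_id),
                elements=tuple(elements),
                normative=normative,
            )
        )

    repo = TemplateRepository(repo_id, templates, value_sets)
    repo.validate()
    logger.info(
        "Parsed template repository %s: %d templates (%d normative), %d value-set versions",
        repo_id,
        len(templates),
        len(repo.normative_templates()),
        len(value_sets),
    )
    return repo


def write_template_repository(repo: TemplateRepository) -> str:
    """Serialize a template repository.

    Exists to let the synthetic-fixture generator emit parseable BBR files
    (and to support round-trip testing); not intended as an authoring tool.
    """
    root = etree.Element("decor", project=repo.repository_id)
    normative_ids = sorted({t.template_id for t in repo.templates if t.normative})
    for t in repo.templates:
        t_el = etree.SubElement(
            root,
            "template",
            id=t.template_id,
            effectiveDate=t.effective_date,
            name=t.name,
        )
        for e in t.elements:
            e_el = etree.SubElement(
                t_el,
                "element",
                id=e.element_id,
                name=e.path,
                contentKind=e.content_kind.value,
            )
            if isinstance(e.binding, FixedBinding):
                etree.SubElement(e_el, "code", **_code_attrs(e.binding.code))
            elif isinstance(e.binding, ValueSetBinding):
                attrs = {"valueSet": e.binding.valueset_id}
                if e.binding.effective_date is not None:
                    attrs["effectiveDate"] = e.binding.effective_date
                etree.SubElement(e_el, "vocabulary", **attrs)
    for vs in repo.value_sets:
        vs_el = etree.SubElement(
            root, "valueSet", id=vs.valueset_id, effectiveDate=vs.effective_date
        )
        if vs.name:
            vs_el.set("name", vs.name)
        cl = etree.SubElement(vs_el, "conceptList")
        for code in sorted(vs.codes):
            etree.SubElement(cl, "concept", **_code_attrs(code))
    if normative_ids:
        dt_el = etree.SubElement(root, "documentType", id="dt-normative", status="Normative")
        for tid in normative_ids:
            etree.SubElement(dt_el, "templateRef", ref=tid)
    non_norm = sorted({t.template_id for t in repo.templates if not t.normative})
    non_norm = [tid for tid in non_norm if tid not in normative_ids]
    if non_norm:
        dt_el = etree.SubElement(root, "documentType", id="dt-draft", status="Draft")
        for tid in non_norm:
            etree.SubElement(dt_el, "templateRef", ref=tid)
    return etree.tostring(
        root, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    ).decode("utf-8")


# ---------------------------------------------------------------------------
# template associations
# ---------------------------------------------------------------------------


def parse_associations(xml_text: Union[str, bytes]) -> AssociationDocument:
    root = _root(xml_text)
    project_id = _require(root, "project")
    seen: set[TemplateAssociation] = set()
    for a_el in root.findall("templateAssociation"):
        qualifier = None
        q_code = a_el.get("qualifierCode")
        if q_code is not None:
            qualifier = Code(
                system=_require(a_el, "qualifierCodeSystem"), code=q_code
            )
        assoc = TemplateAssociation(
            concept_id=_require(a_el, "concept"),
            template_id=_require(a_el, "template"),
            template_date=_require(a_el, "effectiveDate"),
            element_ids=tuple(_require(e, "id") for e in a_el.findall("element")),
            qualifier=qualifier,
            provenance=a_el.get("provenance", "manual"),
        )
        if assoc in seen:
            logger.warning(
                "Duplicate template association for concept %r -> %r dropped",
                assoc.concept_id,
                assoc.template_id,
            )
            continue
        seen.add(assoc)
    return AssociationDocument(project_id, frozenset(seen))


def write_associations(doc: AssociationDocument) -> str:
    root = etree.Element("decor", project=doc.project_id)
    for a in doc.sorted_associations():
        attrs = {
            "concept": a.concept_id,
            "template": a.template_id,
            "effectiveDate": a.template_date,
            "provenance": a.provenance,
        }
        if a.qualifier is not None:
            attrs["qualifierCode"] = a.qualifier.code
            attrs["qualifierCodeSystem"] = a.qualifier.system
        a_el = etree.SubElement(root, "templateAssociation", **attrs)
        for eid in a.element_ids:
            etree.SubElement(a_el, "element", id=eid)
    return etree.tostring(
        root, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    ).decode("utf-8")


# ---------------------------------------------------------------------------
# YAML report
# ---------------------------------------------------------------------------


def write_report_yaml(report) -> str:
    """Serialize a coverage report to YAML with a fixed, sorted key schema.

    Byte-identical for identical reports (keys sorted, block style).
    """
    return yaml.safe_dump(report.to_mapping(), sort_keys=True, default_flow_style=False)


def parse_report_yaml(yaml_text: str) -> dict:
    return yaml.safe_load(yaml_text)


# ---------------------------------------------------------------------------
# remote retrieval
# ---------------------------------------------------------------------------


def fetch_project(url: str, timeout: float = 30.0) -> str:
    """Fetch a project file over HTTP(S) and return the raw XML text.

    Convenience for pulling exports from a REST endpoint; errors surface to
    the caller, nothing is retried.  All other functionality works offline.
    """
    with urllib.request.urlopen(url, timeout=timeout) as resp:  # noqa: S310
        return resp.read().decode("utf-8")
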