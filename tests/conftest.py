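import pytest

from cdacover import fixtures, pipeline
from cdacover.matcher import CodeOccurrence
from cdacover.model import (
    Code,
    ContentKind,
    FixedBinding,
    Template,
    TemplateElement,
    TemplateRepository,
    ValueSet,
    ValueSetBinding,
)


@pytest.fixture(scope="session")
def elga_bundle():
    return fixtures.generate(fixtures.elga_preset(seed=1))


@pytest.fixture(scope="session")
def elga_results(elga_bundle):
    """(report, merged associations, accepted candidates) of the full
    accept-all workflow on the ELGA-like preset."""
    return pipeline.run_coverage(
        elga_bundle.concepts,
        elga_bundle.crosswalk,
        [elga_bundle.templates],
        [elga_bundle.manual_associations],
    )


def make_generic_lab_repo(extra_version: bool = False) -> TemplateRepository:
    """A minimal repository with one generic lab-observation template:
    value-set bound code element plus an unbound quantity value element."""
    value_sets = [
        ValueSet(
            "vs-lab",
            "2021-06-01",
            frozenset({Code("FAKE-LOINC", "L-1"), Code("FAKE-LOINC", "L-2")}),
        )
    ]
    if extra_version:
        value_sets.append(
            ValueSet(
                "vs-lab",
                "2019-04-01",
                frozenset({Code("FAKE-LOINC", "L-1"), Code("FAKE-LOINC", "L-2")}),
            )
        )
    template = Template(
        "t-lab",
        "2021-01-01",
        "Laboratory Observation",
        (
            TemplateElement("e-code", "hl7:code", ContentKind.CODED, ValueSetBinding("vs-lab")),
            TemplateElement("e-value", "hl7:value", ContentKind.QUANTITY),
        ),
        normative=True,
    )
    return TemplateRepository("bbr-test", [template], value_sets)


def brute_force_occurrences(expanded_sets, repos, normative_only=True):
    """Independent oracle for the matcher: naive nested loops over concept
    codes x templates x elements x bound codes."""
    hits: dict[str, set[CodeOccurrence]] = {}
    for exp in expanded_sets:
        for code in exp.codes:
            for repo in repos:
                for t in repo.templates:
                    if normative_only and not t.normative:
                        continue
                    for el in t.elements:
                        if isinstance(el.binding, FixedBinding):
                            if el.binding.code == code:
                                hits.setdefault(exp.concept_id, set()).add(
                                    CodeOccurrence(
                                        code, t.template_id, t.effective_date, el.element_id, "fixed"
                                    )
                                )
                        elif isinstance(el.binding, ValueSetBinding):
                            for vs in repo.resolve_binding(el.binding):
                                if code in vs.codes:
                                    hits.setdefault(exp.concept_id, set()).add(
                                        CodeOccurrence(
                                            code,
                                            t.template_id,
                                            t.effective_date,
                                            el.element_id,
                                            "valueset",
                                            vs.valueset_id,
                                            vs.effective_date,
                                        )
                                    )
    return hits
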