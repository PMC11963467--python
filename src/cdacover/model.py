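"""Domain model for trial-concept repositories and CDA template repositories.

The model mirrors the structure of DECOR-style artefacts: *datasets* of
hierarchically grouped *concepts* (the data elements a clinical trial needs,
annotated with terminology codes), and *templates* (constraint specifications
on CDA document content, identified by OID + effective date) whose elements
carry terminology bindings.  A concept repository may share data elements
between datasets through inheritance from a common "basic" dataset.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Union

logger = logging.getLogger(__name__)

__all__ = [
    "Code",
    "ConceptDataType",
    "UseCase",
    "Inherited",
    "Concept",
    "Dataset",
    "ConceptRepository",
    "ContentKind",
    "FixedBinding",
    "ValueSetBinding",
    "TemplateElement",
    "Template",
    "ValueSet",
    "TemplateRepository",
    "canonical_system",
    "normalize_data_type",
    "resolve_inheritance",
    "code_system_coverage",
    "ModelError",
    "InheritanceError",
]


class ModelError(ValueError):
    """Invalid domain object or unresolvable reference."""


class InheritanceError(ModelError):
    """Dangling or cyclic concept-inheritance reference."""


# ---------------------------------------------------------------------------
# code systems
# ---------------------------------------------------------------------------

#: OID -> canonical short name, for the code systems that occur in CDA
#: template repositories.  BBR exports mix OIDs and names; comparisons are
#: always on the canonical short form.
OID_REGISTRY: dict[str, str] = {
    "2.16.840.1.113883.6.1": "LOINC",
    "2.16.840.1.113883.6.96": "SNOMED-CT",
    "2.16.840.1.113883.6.3": "ICD-10",
    "2.16.840.1.113883.6.90": "ICD-10-CM",
    "2.16.840.1.113883.6.73": "ATC",
    "2.16.840.1.113883.6.86": "UMLS",
    "2.16.840.1.113883.5.1": "AdministrativeGender",
}

_NAME_ALIASES: dict[str, str] = {
    "SNOMED CT": "SNOMED-CT",
    "SNOMEDCT": "SNOMED-CT",
    "SCT": "SNOMED-CT",
    "ICD10": "ICD-10",
    "ICD-10-WHO": "ICD-10",
}


def canonical_system(system: str) -> str:
    """Normalize a code-system identifier (OID or name) to its short name.

    Unknown systems pass through unchanged (after whitespace trimming), so
    project-local or synthetic systems remain usable.
    """
    s = system.strip()
    if s in OID_REGISTRY:
        return OID_REGISTRY[s]
    return _NAME_ALIASES.get(s.upper(), s)


@dataclass(frozen=True, order=True)
class Code:
    """A terminology code: (code system, code token) plus optional label.

    Equality and ordering are on the canonical (system, code) pair only;
    the display name is carried along but never compared.
    """

    system: str
    code: str
    display: Optional[str] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        sys_c = canonical_system(self.system)
        code_c = self.code.strip()
        if not sys_c or not code_c:
            raise ModelError(f"Code requires non-empty system and code, got {self!r}")
        object.__setattr__(self, "system", sys_c)
        object.__setattr__(self, "code", code_c)


# ---------------------------------------------------------------------------
# concepts
# ---------------------------------------------------------------------------


class ConceptDataType(str, enum.Enum):
    """Closed set of data types a trial concept can take."""

    QUANTITY = "Quantity"
    CODE = "Code"
    COUNT = "Count"
    BOOLEAN = "Boolean"
    DATE = "Date"
    TEXT = "Text"
    IDENTIFIER = "Identifier"


class UseCase(str, enum.Enum):
    """Trial-conduct use case a dataset serves; ``basic`` holds shared elements."""

    FEASIBILITY = "feasibility"
    RECRUITMENT = "recruitment"
    EXECUTION = "execution"
    BASIC = "basic"


@dataclass(frozen=True)
class Inherited:
    """Provenance of an inherited concept: where its payload comes from."""

    source_dataset: str
    source_concept: str


@dataclass(frozen=True)
class Concept:
    """One trial-relevant data element.

    ``data_type`` may be ``None`` only on an inherited stub that has not yet
    been materialized by :func:`resolve_inheritance`.  The same ``id`` may
    appear in several datasets of a repository — that always denotes the same
    (shared, inherited) concept.
    """

    id: str
    name: str
    data_type: Optional[ConceptDataType]
    group_path: tuple[str, ...]
    description: str = ""
    codes: frozenset[Code] = frozenset()
    origin: Optional[Inherited] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelError("Concept id must be non-empty")
        if not self.group_path:
            raise ModelError(f"Concept {self.id!r}: group_path must be non-empty")
        object.__setattr__(self, "group_path", tuple(self.group_path))
        object.__setattr__(self, "codes", frozenset(self.codes))

    @property
    def is_inherited(self) -> bool:
        return self.origin is not None

    @property
    def group(self) -> str:
        """Top-level group label (deeper nesting collapsed)."""
        return self.group_path[0]


@dataclass
class Dataset:
    id: str
    name: str
    use_case: UseCase
    concepts: list[Concept] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for c in self.concepts:
            if c.id in seen:
                raise ModelError(f"Dataset {self.id!r}: duplicate concept {c.id!r}")
            seen.add(c.id)

    def concept(self, concept_id: str) -> Concept:
        for c in self.concepts:
            if c.id == concept_id:
                return c
        raise KeyError(concept_id)


@dataclass
class ConceptRepository:
    project_id: str
    datasets: list[Dataset] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [d.id for d in self.datasets]
        if len(ids) != len(set(ids)):
            raise ModelError(f"Repository {self.project_id!r}: duplicate dataset ids")

    def dataset(self, dataset_id: str) -> Dataset:
        for d in self.datasets:
            if d.id == dataset_id:
                return d
        raise KeyError(dataset_id)

    def use_case_datasets(self) -> list[Dataset]:
        """The datasets that count toward coverage (everything but ``basic``)."""
        return [d for d in self.datasets if d.use_case is not UseCase.BASIC]

    def n_concept_instances(self) -> int:
        """Total concept count, a shared concept counted once per use case."""
        return sum(len(d.concepts) for d in self.use_case_datasets())


# ---------------------------------------------------------------------------
# data-type normalization
# ---------------------------------------------------------------------------

_SOURCE_TYPES = {"Float", "Integer", "Text", "String", "Date", "Boolean"}

# fallback when no semantic hint applies; Float/Integer have no literal
# counterpart in the target enumeration
_IDENTITY = {
    "Text": ConceptDataType.TEXT,
    "String": ConceptDataType.TEXT,
    "Date": ConceptDataType.DATE,
    "Boolean": ConceptDataType.BOOLEAN,
    "Float": ConceptDataType.QUANTITY,
    "Integer": ConceptDataType.COUNT,
}


def normalize_data_type(source_type: str, semantic_hint: str = "none") -> ConceptDataType:
    """Map a source data-type label to the concept data-type enumeration.

    Source labels are the generic types used in medical-data-model exports
    (Float, Integer, Text, String, Date, Boolean).  The semantic hint
    (``"quantity"``, ``"code"``, ``"count"`` or ``"none"``) refines the
    mapping: lab values and vital signs recorded as Float/Integer/Text become
    ``Quantity``; coded fields recorded as String/Text/Integer become
    ``Code``; counted things recorded as Integer/Float become ``Count``.
    Otherwise the label maps to its closest enumeration member.
    """
    label = source_type.strip()
    if label not in _SOURCE_TYPES:
        raise ModelError(
            f"Unknown source data type {source_type!r}; expected one of "
            f"{sorted(_SOURCE_TYPES)}"
        )
    if semantic_hint not in {"quantity", "code", "count", "none"}:
        raise ModelError(f"Unknown semantic hint {semantic_hint!r}")
    if semantic_hint == "quantity" and label in {"Float", "Integer", "Text"}:
        return ConceptDataType.QUANTITY
    if semantic_hint == "code" and label in {"String", "Text", "Integer"}:
        return ConceptDataType.CODE
    if semantic_hint == "count" and label in {"Integer", "Float"}:
        return ConceptDataType.COUNT
    return _IDENTITY[label]


# ---------------------------------------------------------------------------
# inheritance resolution
# ---------------------------------------------------------------------------


def _resolve_root(
    repo: ConceptRepository,
    dataset_id: str,
    concept: Concept,
    _seen: set[tuple[str, str]],
) -> Concept:
    if concept.origin is None:
        return concept
    key = (dataset_id, concept.id)
    if key in _seen:
        chain = " -> ".join(f"{d}/{c}" for d, c in _seen)
        raise InheritanceError(f"Inheritance cycle involving {chain}")
    _seen.add(key)
    src = concept.origin
    try:
        src_ds = repo.dataset(src.source_dataset)
        src_concept = src_ds.concept(src.source_concept)
    except KeyError:
        raise InheritanceError(
            f"Concept {concept.id!r} in dataset {dataset_id!r} inherits from "
            f"{src.source_concept!r} in dataset {src.source_dataset!r}, "
            "which does not exist"
        ) from None
    return _resolve_root(repo, src.source_dataset, src_concept, _seen)


def resolve_inheritance(repo: ConceptRepository) -> ConceptRepository:
    """Materialize inherited concepts: copy payload from their source.

    Every inherited concept receives the source concept's data type, codes
    and description (its own group placement and origin are preserved).
    Per-dataset concept counts are unchanged — a shared concept still appears
    once in each dataset that inherits it.  Idempotent.
    """
    new_datasets: list[Dataset] = []
    for ds in repo.datasets:
        new_concepts: list[Concept] = []
        for c in ds.concepts:
            if c.origin is None:
                new_concepts.append(c)
                continue
            root = _resolve_root(repo, ds.id, c, set())
            new_concepts.append(
                replace(
                    c,
                    name=c.name or root.name,
                    data_type=root.data_type,
                    codes=root.codes,
                    description=root.description,
                )
            )
        new_datasets.append(Dataset(ds.id, ds.name, ds.use_case, new_concepts))
    return ConceptRepository(repo.project_id, new_datasets)


def code_system_coverage(repo: ConceptRepository, system: str) -> tuple[int, int]:
    """(n_with_code, n_total) of use-case concept instances carrying at least
    one code from ``system`` (canonical form).  Shared concepts count once per
    use case."""
    sys_c = canonical_system(system)
    total = 0
    with_code = 0
    for ds in repo.use_case_datasets():
        for c in ds.concepts:
            total += 1
            if any(code.system == sys_c for code in c.codes):
                with_code += 1
    return with_code, total


# ---------------------------------------------------------------------------
# templates
# ---------------------------------------------------------------------------


class ContentKind(str, enum.Enum):
    CODED = "coded"
    QUANTITY = "quantity"
    DATETIME = "datetime"
    BOOLEAN = "boolean"
    NARRATIVE_TEXT = "narrative_text"


@dataclass(frozen=True)
class FixedBinding:
    """Element content fixed to a single code."""

    code: Code


@dataclass(frozen=True)
class ValueSetBinding:
    """Element content drawn from a value set; ``effective_date=None`` binds
    whatever versions the repository holds."""

    valueset_id: str
    effective_date: Optional[str] = None


Binding = Union[FixedBinding, ValueSetBinding]


@dataclass(frozen=True)
class TemplateElement:
    element_id: str
    path: str
    content_kind: ContentKind
    binding: Optional[Binding] = None

    def __post_init__(self) -> None:
        if self.content_kind is ContentKind.NARRATIVE_TEXT and self.binding is not None:
            raise ModelError(
                f"Element {self.element_id!r}: narrative text cannot carry a binding"
            )
        if self.binding is not None and self.content_kind is not ContentKind.CODED:
            raise ModelError(
                f"Element {self.element_id!r}: terminology bindings are only "
                "valid on coded elements"
            )


@dataclass(frozen=True)
class Template:
    """A CDA template version: OID-like id + effective date, with elements.

    ``normative`` marks templates referenced from a document type of status
    "Normative" — only those describe data structures live in the EHR system.
    """

    template_id: str
    effective_date: str
    name: str
    elements: tuple[TemplateElement, ...]
    normative: bool = False

    def __post_init__(self) -> None:
        if not self.elements:
            raise ModelError(f"Template {self.template_id!r} has no elements")
        ids = [e.element_id for e in self.elements]
        if len(ids) != len(set(ids)):
            raise ModelError(f"Template {self.template_id!r}: duplicate element ids")

    def element(self, element_id: str) -> TemplateElement:
        for e in self.elements:
            if e.element_id == element_id:
                return e
        raise KeyError(element_id)


@dataclass(frozen=True)
class ValueSet:
    valueset_id: str
    effective_date: str
    codes: frozenset[Code]
    name: str = ""

    def __post_init__(self) -> None:
        if not self.codes:
            raise ModelError(f"Value set {self.valueset_id!r} is empty")
        object.__setattr__(self, "codes", frozenset(self.codes))


@dataclass
class TemplateRepository:
    """A building-block repository: template versions plus value-set versions."""

    repository_id: str
    templates: list[Template] = field(default_factory=list)
    value_sets: list[ValueSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        tkeys = [(t.template_id, t.effective_date) for t in self.templates]
        if len(tkeys) != len(set(tkeys)):
            raise ModelError("Duplicate (template_id, effective_date) in repository")
        vkeys = [(v.valueset_id, v.effective_date) for v in self.value_sets]
        if len(vkeys) != len(set(vkeys)):
            raise ModelError("Duplicate (valueset_id, effective_date) in repository")

    def template(self, template_id: str, effective_date: str) -> Template:
        for t in self.templates:
            if t.template_id == template_id and t.effective_date == effective_date:
                return t
        raise KeyError((template_id, effective_date))

    def valueset_versions(self, valueset_id: str) -> list[ValueSet]:
        """All versions of a value set, oldest first (dates are ISO strings,
        compared lexicographically)."""
        vs = [v for v in self.value_sets if v.valueset_id == valueset_id]
        return sorted(vs, key=lambda v: v.effective_date)

    def resolve_binding(self, binding: ValueSetBinding) -> list[ValueSet]:
        versions = self.valueset_versions(binding.valueset_id)
        if binding.effective_date is not None:
            versions = [v for v in versions if v.effective_date == binding.effective_date]
        return versions

    def validate(self) -> None:
        """Check that every value-set binding resolves to >=1 version."""
        for t in self.templates:
            for e in t.elements:
                if isinstance(e.binding, ValueSetBinding):
                    if not self.resolve_binding(e.binding):
                        raise ModelError(
                            f"Template {t.template_id!r}/{t.effective_date} element "
                            f"{e.element_id!r}: value-set binding "
                            f"{e.binding.valueset_id!r} (date "
                            f"{e.binding.effective_date!r}) does not resolve"
                        )

    def normative_templates(self) -> list[Template]:
        return [t for t in self.templates if t.normative]
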