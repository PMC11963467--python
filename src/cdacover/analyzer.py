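"""Coverage statistics: which trial concepts an EHR system can record.

Given a (resolved) concept repository, the merged template associations and
the template repositories they point into, each concept in each use-case
dataset is classified as unmapped, mapped to free text only, or mapped to at
least one structured element — a concept reaching both a structured and a
free-text target counts as structured.  Counts and integer percentages are
reported per use case, per top-level concept group within the use case, and
overall; a concept shared between use cases is counted once in each.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

from .associations import AssociationDocument, TemplateAssociation
from .model import (
    Concept,
    ConceptRepository,
    ContentKind,
    ModelError,
    TemplateElement,
    TemplateRepository,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MappingStatus",
    "ElementClass",
    "CoverageRow",
    "CoverageReport",
    "AnalysisError",
    "classify_element",
    "classify_concept",
    "analyze",
    "pct",
]


class AnalysisError(ValueError):
    """Association points at content that cannot be resolved."""


class MappingStatus(str, enum.Enum):
    UNMAPPED = "unmapped"
    MAPPED_FREE_TEXT = "mapped_free_text"
    MAPPED_STRUCTURED = "mapped_structured"


class ElementClass(str, enum.Enum):
    STRUCTURED = "structured"
    FREE_TEXT = "free_text"


def pct(numerator: int, denominator: int) -> int:
    """Integer percentage, rounded half up (the rounding that reproduces the
    printed coverage tables); 0 for an empty denominator."""
    if denominator == 0:
        return 0
    return int(
        (Decimal(100 * numerator) / Decimal(denominator)).quantize(
            Decimal("1"), rounding=ROUND_HALF_UP
        )
    )


def classify_element(el: TemplateElement) -> ElementClass:
    """Narrative text is free text; coded, quantity, datetime and boolean
    content is structured."""
    if el.content_kind is ContentKind.NARRATIVE_TEXT:
        return ElementClass.FREE_TEXT
    return ElementClass.STRUCTURED


def _find_template(repos: Sequence[TemplateRepository], assoc: TemplateAssociation):
    for repo in repos:
        try:
            return repo.template(assoc.template_id, assoc.template_date)
        except KeyError:
            continue
    return None


def classify_concept(
    concept_id: str,
    associations: Iterable[TemplateAssociation],
    repos: Sequence[TemplateRepository],
) -> MappingStatus:
    """Mapping status of one concept given its associations.

    Any association touching at least one structured element makes the
    concept structured; otherwise any association at all makes it free-text;
    none leaves it unmapped.  Associations into non-normative templates are
    flagged and ignored — those templates describe no live data structure.
    An association whose template or element cannot be found is an error.
    """
    status = MappingStatus.UNMAPPED
    for assoc in associations:
        template = _find_template(repos, assoc)
        if template is None:
            raise AnalysisError(
                f"Association for concept {concept_id!r} points at unknown "
                f"template {assoc.template_id!r} ({assoc.template_date})"
            )
        if not template.normative:
            logger.warning(
                "Association for concept %r targets non-normative template %r; ignored",
                concept_id,
                template.name,
            )
            continue
        for eid in assoc.element_ids:
            try:
                el = template.element(eid)
            except KeyError:
                raise AnalysisError(
                    f"Association for concept {concept_id!r}: element {eid!r} "
                    f"not in template {assoc.template_id!r}"
                ) from None
            if classify_element(el) is ElementClass.STRUCTURED:
                return MappingStatus.MAPPED_STRUCTURED
        status = MappingStatus.MAPPED_FREE_TEXT
    return status


@dataclass
class CoverageRow:
    label: str
    n_concepts: int
    n_mapped: int
    n_structured: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_structured <= self.n_mapped <= self.n_concepts:
            raise ModelError(
                f"Row {self.label!r}: need 0 <= structured <= mapped <= concepts, "
                f"got {self.n_structured}/{self.n_mapped}/{self.n_concepts}"
            )

    @property
    def pct_mapped(self) -> int:
        return pct(self.n_mapped, self.n_concepts)

    @property
    def pct_structured(self) -> int:
        return pct(self.n_structured, self.n_concepts)

    def to_mapping(self) -> dict:
        return {
            "label": self.label,
            "concepts": self.n_concepts,
            "mapped": self.n_mapped,
            "mapped_pct": self.pct_mapped,
            "structured": self.n_structured,
            "structured_pct": self.pct_structured,
        }


@dataclass
class UseCaseRow(CoverageRow):
    groups: list[CoverageRow] = field(default_factory=list)

    def to_mapping(self) -> dict:
        out = super().to_mapping()
        out["groups"] = [g.to_mapping() for g in self.groups]
        return out


@dataclass
class CoverageReport:
    use_cases: list[UseCaseRow]
    overall: CoverageRow

    def validate(self) -> None:
        """Additivity: overall = sum of use cases; use case = sum of groups."""
        for attr in ("n_concepts", "n_mapped", "n_structured"):
            total = sum(getattr(r, attr) for r in self.use_cases)
            if total != getattr(self.overall, attr):
                raise ModelError(
                    f"Overall {attr} ({getattr(self.overall, attr)}) != "
                    f"sum over use cases ({total})"
                )
            for r in self.use_cases:
                gsum = sum(getattr(g, attr) for g in r.groups)
                if gsum != getattr(r, attr):
                    raise ModelError(
                        f"Use case {r.label!r} {attr} ({getattr(r, attr)}) != "
                        f"sum over groups ({gsum})"
                    )

    def to_mapping(self) -> dict:
        return {
            "overall": self.overall.to_mapping(),
            "use_cases": [r.to_mapping() for r in self.use_cases],
        }

    def use_case(self, label: str) -> UseCaseRow:
        for r in self.use_cases:
            if r.label == label:
                return r
        raise KeyError(label)


def analyze(
    repo: ConceptRepository,
    associations: AssociationDocument,
    template_repos: Sequence[TemplateRepository],
) -> CoverageReport:
    """Compute the coverage report.

    ``repo`` must have inheritance resolved.  Associations are keyed by
    concept id, so a concept shared between use cases gets the same status
    in each — but is counted once per use case, by design.  Group rows are
    keyed by the top-level group label, in first-appearance order.
    """
    by_concept: dict[str, list[TemplateAssociation]] = {}
    for a in associations.sorted_associations():
        by_concept.setdefault(a.concept_id, []).append(a)

    status_cache: dict[str, MappingStatus] = {}

    def status_of(concept: Concept) -> MappingStatus:
        if concept.id not in status_cache:
            status_cache[concept.id] = classify_concept(
                concept.id, by_concept.get(concept.id, ()), template_repos
            )
        return status_cache[concept.id]

    use_case_rows: list[UseCaseRow] = []
    for ds in repo.use_case_datasets():
        group_counts: dict[str, list[int]] = {}
        group_order: list[str] = []
        for c in ds.concepts:
            if c.group not in group_counts:
                group_counts[c.group] = [0, 0, 0]
                group_order.append(c.group)
            counts = group_counts[c.group]
            s = status_of(c)
            counts[0] += 1
            if s is not MappingStatus.UNMAPPED:
                counts[1] += 1
            if s is MappingStatus.MAPPED_STRUCTURED:
                counts[2] += 1
        groups = [
            CoverageRow(g, *group_counts[g]) for g in group_order
        ]
        use_case_rows.append(
            UseCaseRow(
                label=ds.name,
                n_concepts=sum(g.n_concepts for g in groups),
                n_mapped=sum(g.n_mapped for g in groups),
                n_structured=sum(g.n_structured for g in groups),
                groups=groups,
            )
        )

    overall = CoverageRow(
        "Overall",
        n_concepts=sum(r.n_concepts for r in use_case_rows),
        n_mapped=sum(r.n_mapped for r in use_case_rows),
        n_structured=sum(r.n_structured for r in use_case_rows),
    )
    report = CoverageReport(use_cases=use_case_rows, overall=overall)
    report.validate()
    return report
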