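"""Template associations: formal concept-to-template-element mappings.

A template association links one trial concept to the element(s) of a CDA
template that can hold its data.  A mapping onto a *generic* template (for
example a laboratory observation specialized by its own ``code`` element)
spans two elements — the code element and the value element — and carries the
specializing code as a qualifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .model import Code, ModelError

__all__ = ["Provenance", "TemplateAssociation", "AssociationDocument"]

#: how a mapping came about: produced by the automatic code-based matcher, or
#: hand-authored by someone familiar with the EHR system's templates
PROVENANCE_VALUES = ("automatic", "manual")


@dataclass(frozen=True)
class TemplateAssociation:
    concept_id: str
    template_id: str
    template_date: str
    element_ids: tuple[str, ...]
    qualifier: Optional[Code] = None
    provenance: str = "manual"

    def __post_init__(self) -> None:
        if not self.element_ids:
            raise ModelError("TemplateAssociation needs at least one element id")
        if self.provenance not in PROVENANCE_VALUES:
            raise ModelError(
                f"provenance must be one of {PROVENANCE_VALUES}, "
                f"got {self.provenance!r}"
            )
        object.__setattr__(self, "element_ids", tuple(self.element_ids))


@dataclass
class AssociationDocument:
    """A project file of template associations; order-insensitive container."""

    project_id: str
    associations: frozenset[TemplateAssociation] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "associations", frozenset(self.associations))

    def sorted_associations(self) -> list[TemplateAssociation]:
        """Deterministic listing, for serialization and reports."""
        return sorted(
            self.associations,
            key=lambda a: (a.concept_id, a.template_id, a.template_date, a.element_ids),
        )

    def merge(self, other: "AssociationDocument") -> "AssociationDocument":
        return AssociationDocument(
            self.project_id, self.associations | other.associations
        )


def merge_documents(docs: Iterable[AssociationDocument], project_id: str = "merged") -> AssociationDocument:
    merged: frozenset[TemplateAssociation] = frozenset()
    for d in docs:
        merged = merged | d.associations
    return AssociationDocument(project_id, merged)
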