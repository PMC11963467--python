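"""Automatic code-based matching of expanded concept codes against templates.

The matcher scans the normative templates of one or more building-block
repositories for occurrences of any code in a concept's expanded code set —
in fixed-code bindings or in bound value sets.  Hits become candidate
matches, which a reviewer accepts or rejects; accepted candidates are turned
into formal template associations.  Matching is exact on the canonical
(system, code) pair: no lexical or display-name matching is attempted, since
label matching is known to both miss and fabricate equivalences — that part
of the work stays manual.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence, Union

from .associations import TemplateAssociation
from .model import (
    Code,
    ContentKind,
    FixedBinding,
    ModelError,
    Template,
    TemplateElement,
    TemplateRepository,
    ValueSetBinding,
)
from .vocab import ExpandedCodeSet

logger = logging.getLogger(__name__)

__all__ = [
    "CodeOccurrence",
    "GroupedOccurrence",
    "CandidateMatch",
    "MatchError",
    "index_codes",
    "match",
    "consolidate",
    "to_associations",
]


class MatchError(ValueError):
    """Candidate refers to template content that no longer resolves."""


@dataclass(frozen=True, order=True)
class CodeOccurrence:
    """One place a code occurs in a template repository."""

    code: Code
    template_id: str
    template_date: str
    element_id: str
    #: "fixed" for a fixed-code binding, "valueset" for value-set membership
    via: str
    valueset_id: Optional[str] = None
    valueset_date: Optional[str] = None


@dataclass(frozen=True, order=True)
class GroupedOccurrence:
    """Occurrences on one template element after consolidation.

    Value-set duplicates across versions are collapsed to the latest version
    and all codes hitting the same (template, element, value set) are grouped
    into one record.
    """

    template_id: str
    template_date: str
    element_id: str
    via: str
    valueset_id: Optional[str]
    valueset_date: Optional[str]
    codes: tuple[Code, ...]


Occurrence = Union[CodeOccurrence, GroupedOccurrence]

PENDING = "pending"
ACCEPTED = "accepted"
REJECTED = "rejected"


@dataclass(frozen=True)
class CandidateMatch:
    """A concept with at least one code hit, awaiting manual validation."""

    concept_id: str
    occurrences: frozenset
    status: str = PENDING
    reject_reason: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.occurrences:
            raise ModelError(f"Candidate {self.concept_id!r} has no occurrences")
        object.__setattr__(self, "occurrences", frozenset(self.occurrences))

    def accept(self) -> "CandidateMatch":
        if self.status != PENDING:
            raise ModelError(f"Candidate {self.concept_id!r} already {self.status}")
        return replace(self, status=ACCEPTED)

    def reject(self, reason: str) -> "CandidateMatch":
        if self.status != PENDING:
            raise ModelError(f"Candidate {self.concept_id!r} already {self.status}")
        return replace(self, status=REJECTED, reject_reason=reason)

    def matched_codes(self) -> frozenset[Code]:
        out: set[Code] = set()
        for occ in self.occurrences:
            if isinstance(occ, GroupedOccurrence):
                out.update(occ.codes)
            else:
                out.add(occ.code)
        return frozenset(out)


# ---------------------------------------------------------------------------
# index + scan
# ---------------------------------------------------------------------------


def index_codes(
    repo: TemplateRepository, normative_only: bool = True
) -> dict[Code, frozenset[CodeOccurrence]]:
    """Build the code index: every code bound anywhere in the repository,
    mapped to the set of places it occurs.

    Only fixed-code bindings and the value-set contents of a template's
    direct elements are scanned; by default non-normative templates are
    skipped because they describe no data structure live in the system.
    """
    out: dict[Code, set[CodeOccurrence]] = {}
    templates = repo.normative_templates() if normative_only else repo.templates
    for t in templates:
        for el in t.elements:
            if isinstance(el.binding, FixedBinding):
                occ = CodeOccurrence(
                    code=el.binding.code,
                    template_id=t.template_id,
                    template_date=t.effective_date,
                    element_id=el.element_id,
                    via="fixed",
                )
                out.setdefault(el.binding.code, set()).add(occ)
            elif isinstance(el.binding, ValueSetBinding):
                for vs in repo.resolve_binding(el.binding):
                    for code in vs.codes:
                        occ = CodeOccurrence(
                            code=code,
                            template_id=t.template_id,
                            template_date=t.effective_date,
                            element_id=el.element_id,
                            via="valueset",
                            valueset_id=vs.valueset_id,
                            valueset_date=vs.effective_date,
                        )
                        out.setdefault(code, set()).add(occ)
    return {code: frozenset(occs) for code, occs in out.items()}


def merge_indexes(
    indexes: Iterable[dict[Code, frozenset[CodeOccurrence]]]
) -> dict[Code, frozenset[CodeOccurrence]]:
    """Union the code indexes of several building-block repositories."""
    out: dict[Code, frozenset[CodeOccurrence]] = {}
    for index in indexes:
        for code, occs in index.items():
            out[code] = out.get(code, frozenset()) | occs
    return out


def match(
    expanded: Sequence[ExpandedCodeSet],
    index: dict[Code, frozenset[CodeOccurrence]],
) -> list[CandidateMatch]:
    """Scan the index for each concept's expanded codes.

    One pending candidate per concept with at least one hit; concepts
    without hits are absent.  Output ordered by concept id.
    """
    candidates: list[CandidateMatch] = []
    for exp in sorted(expanded, key=lambda e: e.concept_id):
        occs: set[CodeOccurrence] = set()
        for code in exp.codes:
            occs.update(index.get(code, ()))
        if occs:
            candidates.append(CandidateMatch(exp.concept_id, frozenset(occs)))
    return candidates


# ---------------------------------------------------------------------------
# consolidation
# ---------------------------------------------------------------------------


def _occurrence_parts(occ: Occurrence):
    """(grouping key without vs date, vs date, codes)"""
    if isinstance(occ, GroupedOccurrence):
        return (
            (occ.template_id, occ.template_date, occ.element_id, occ.via, occ.valueset_id),
            occ.valueset_date,
            set(occ.codes),
        )
    return (
        (occ.template_id, occ.template_date, occ.element_id, occ.via, occ.valueset_id),
        occ.valueset_date,
        {occ.code},
    )


def consolidate(candidates: Sequence[CandidateMatch]) -> list[CandidateMatch]:
    """Deduplicate and group a candidate's occurrences.

    Occurrences differing only in value-set effective date collapse to the
    latest version (dates compared lexicographically); all codes hitting the
    same (template, element, value set) merge into one grouped occurrence
    carrying the full code list.  The candidate set — and hence which
    concepts are matched — is unchanged.  Idempotent.
    """
    out: list[CandidateMatch] = []
    for cand in candidates:
        by_key: dict[tuple, dict[Optional[str], set[Code]]] = {}
        for occ in cand.occurrences:
            key, vs_date, codes = _occurrence_parts(occ)
            by_key.setdefault(key, {}).setdefault(vs_date, set()).update(codes)
        grouped: set[GroupedOccurrence] = set()
        for key, versions in by_key.items():
            template_id, template_date, element_id, via, valueset_id = key
            latest = max(versions, key=lambda d: d or "")
            grouped.add(
                GroupedOccurrence(
                    template_id=template_id,
                    template_date=template_date,
                    element_id=element_id,
                    via=via,
                    valueset_id=valueset_id,
                    valueset_date=latest,
                    codes=tuple(sorted(versions[latest])),
                )
            )
        out.append(replace(cand, occurrences=frozenset(grouped)))
    return out


# ---------------------------------------------------------------------------
# association emission
# ---------------------------------------------------------------------------


def _find_template(repos: Sequence[TemplateRepository], template_id: str, date: str) -> Template:
    for repo in repos:
        try:
            return repo.template(template_id, date)
        except KeyError:
            continue
    raise MatchError(f"Template {template_id!r} ({date}) not found in any repository")


def _generic_value_element(template: Template, code_element: TemplateElement) -> Optional[TemplateElement]:
    """Detect a generic template: the matched coded element is value-set
    bound and a sibling non-narrative, unbound value element exists.  Returns
    that sibling (first in element order) or None."""
    if not isinstance(code_element.binding, ValueSetBinding):
        return None
    for el in template.elements:
        if el.element_id == code_element.element_id:
            continue
        if el.content_kind is ContentKind.NARRATIVE_TEXT:
            continue
        if el.binding is None:
            return el
    return None


def to_associations(
    candidates: Sequence[CandidateMatch],
    repos: Sequence[TemplateRepository],
) -> list[TemplateAssociation]:
    """Convert accepted candidates into template associations.

    One association per (concept, template, element).  A hit on the code
    element of a generic template emits a paired association spanning the
    code element and its value element, carrying the matched code as
    qualifier.  Rejected and pending candidates contribute nothing.
    """
    associations: dict[tuple[str, str, str, tuple[str, ...]], TemplateAssociation] = {}
    for cand in candidates:
        if cand.status != ACCEPTED:
            logger.debug("Skipping %s candidate %r", cand.status, cand.concept_id)
            continue
        for occ in consolidate([cand])[0].occurrences:
            template = _find_template(repos, occ.template_id, occ.template_date)
            try:
                el = template.element(occ.element_id)
            except KeyError:
                raise MatchError(
                    f"Candidate {cand.concept_id!r}: element {occ.element_id!r} "
                    f"not in template {occ.template_id!r}"
                ) from None
            value_el = _generic_value_element(template, el)
            if value_el is not None:
                element_ids = (el.element_id, value_el.element_id)
                if len(occ.codes) == 1:
                    qualifier = occ.codes[0]
                else:
                    logger.warning(
                        "Candidate %r matches %d codes on generic template %r; "
                        "qualifier left open",
                        cand.concept_id,
                        len(occ.codes),
                        template.name,
                    )
                    qualifier = None
            else:
                element_ids = (el.element_id,)
                qualifier = None
            key = (cand.concept_id, occ.template_id, occ.template_date, element_ids)
            associations[key] = TemplateAssociation(
                concept_id=cand.concept_id,
                template_id=occ.template_id,
                template_date=occ.template_date,
                element_ids=element_ids,
                qualifier=qualifier,
                provenance="automatic",
            )
    return [associations[k] for k in sorted(associations)]
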