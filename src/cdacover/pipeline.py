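"""End-to-end orchestration: expand, scan, consolidate, analyze.

Thin glue over the library modules; the CLI and the reproduction script both
go through these functions so there is exactly one definition of the
workflow: expand each concept's codes over the crosswalk, scan the normative
templates for hits, consolidate the candidates, convert the validated ones
into associations, merge in hand-authored association files, and compute the
coverage report.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from .analyzer import CoverageReport, analyze
from .associations import AssociationDocument, TemplateAssociation, merge_documents
from .matcher import (
    CandidateMatch,
    consolidate,
    index_codes,
    match,
    merge_indexes,
    to_associations,
)
from .model import Concept, ConceptRepository, TemplateRepository, resolve_inheritance
from .vocab import Crosswalk, ExpandedCodeSet, expand

__all__ = [
    "unique_concepts",
    "expand_concepts",
    "auto_match",
    "auto_map",
    "matched_instances",
    "run_coverage",
]


def unique_concepts(repo: ConceptRepository) -> list[Concept]:
    """Distinct concepts of the use-case datasets (shared concepts once),
    ordered by id.  Requires resolved inheritance."""
    seen: dict[str, Concept] = {}
    for ds in repo.use_case_datasets():
        for c in ds.concepts:
            seen.setdefault(c.id, c)
    return [seen[cid] for cid in sorted(seen)]


def expand_concepts(repo: ConceptRepository, crosswalk: Crosswalk) -> list[ExpandedCodeSet]:
    return [expand(c, crosswalk) for c in unique_concepts(repo)]


def auto_match(
    repo: ConceptRepository,
    crosswalk: Crosswalk,
    template_repos: Sequence[TemplateRepository],
) -> list[CandidateMatch]:
    """Pending, consolidated candidate matches for every concept with a hit."""
    index = merge_indexes(index_codes(r) for r in template_repos)
    return consolidate(match(expand_concepts(repo, crosswalk), index))


def auto_map(
    repo: ConceptRepository,
    crosswalk: Crosswalk,
    template_repos: Sequence[TemplateRepository],
) -> tuple[list[TemplateAssociation], list[CandidateMatch]]:
    """Accept-all automatic mapping: every candidate validated as accepted.

    Returns the emitted associations and the accepted candidates.
    """
    accepted = [c.accept() for c in auto_match(repo, crosswalk, template_repos)]
    return to_associations(accepted, template_repos), accepted


def matched_instances(repo: ConceptRepository, concept_ids: Iterable[str]) -> int:
    """How many use-case concept instances the given concept ids cover
    (a shared concept counts once per use case)."""
    ids = set(concept_ids)
    return sum(
        1 for ds in repo.use_case_datasets() for c in ds.concepts if c.id in ids
    )


def run_coverage(
    repo: ConceptRepository,
    crosswalk: Crosswalk,
    template_repos: Sequence[TemplateRepository],
    manual_docs: Sequence[AssociationDocument] = (),
    resolve: bool = True,
) -> tuple[CoverageReport, AssociationDocument, list[CandidateMatch]]:
    """The full workflow with accept-all validation of automatic candidates."""
    if resolve:
        repo = resolve_inheritance(repo)
    auto_assocs, accepted = auto_map(repo, crosswalk, template_repos)
    merged = merge_documents(
        [AssociationDocument("auto-mappings", frozenset(auto_assocs)), *manual_docs]
    )
    report = analyze(repo, merged, template_repos)
    return report, merged, accepted
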