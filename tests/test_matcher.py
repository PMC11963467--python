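"""Code index, template scan, candidate consolidation, association emission."""

import pytest

from conftest import brute_force_occurrences, make_generic_lab_repo

from cdacover import fixtures, pipeline
from cdacover.matcher import (
    CandidateMatch,
    CodeOccurrence,
    GroupedOccurrence,
    MatchError,
    consolidate,
    index_codes,
    match,
    merge_indexes,
    to_associations,
)
from cdacover.model import (
    Code,
    ContentKind,
    FixedBinding,
    ModelError,
    Template,
    TemplateElement,
    TemplateRepository,
    ValueSet,
    ValueSetBinding,
    resolve_inheritance,
)
from cdacover.vocab import ExpandedCodeSet


def _exp(cid, *codes):
    return ExpandedCodeSet(concept_id=cid, codes=tuple(sorted(codes)))


def _fixed_repo():
    t = Template(
        "t-fix",
        "2021-01-01",
        "Coded Entry",
        (TemplateElement("e1", "hl7:code", ContentKind.CODED, FixedBinding(Code("FAKE-SNOMED", "F1"))),),
        normative=True,
    )
    return TemplateRepository("bbr-fix", [t], [])


class TestIndexCodes:
    def test_single_fixed_binding(self):
        index = index_codes(_fixed_repo())
        assert set(index) == {Code("FAKE-SNOMED", "F1")}
        (occ,) = index[Code("FAKE-SNOMED", "F1")]
        assert (occ.template_id, occ.element_id, occ.via) == ("t-fix", "e1", "fixed")

    def test_valueset_codes_share_element(self):
        vs = ValueSet("vs", "2021-01-01", frozenset(Code("FAKE-LOINC", f"L{i}") for i in range(5)))
        t = Template(
            "t", "2021-01-01", "T",
            (TemplateElement("e", "hl7:code", ContentKind.CODED, ValueSetBinding("vs")),),
            normative=True,
        )
        index = index_codes(TemplateRepository("b", [t], [vs]))
        assert len(index) == 5
        assert {occ.element_id for occs in index.values() for occ in occs} == {"e"}

    def test_non_normative_templates_skipped_by_default(self):
        repo = _fixed_repo()
        draft = Template(
            "t-draft", "2021-01-01", "Draft",
            (TemplateElement("e9", "hl7:code", ContentKind.CODED, FixedBinding(Code("FAKE-SNOMED", "F1"))),),
            normative=False,
        )
        repo = TemplateRepository("b", repo.templates + [draft], [])
        assert len(index_codes(repo)[Code("FAKE-SNOMED", "F1")]) == 1
        assert len(index_codes(repo, normative_only=False)[Code("FAKE-SNOMED", "F1")]) == 2

    @pytest.mark.parametrize("seed", range(5))
    def test_index_agrees_with_linear_scan(self, seed):
        bundle = fixtures.generate(
            fixtures.FixtureSpec(seed=seed, n_feasibility=15, n_recruitment=15, n_execution=15)
        )
        index = index_codes(bundle.templates)
        exp_sets = [_exp("probe", code) for code in index]
        brute = brute_force_occurrences(exp_sets, [bundle.templates])
        assert {occ for occs in index.values() for occ in occs} == {
            occ for occs in brute.values() for occ in occs
        }


class TestMatch:
    def test_single_hit_single_candidate(self):
        cands = match([_exp("c1", Code("FAKE-SNOMED", "F1"))], index_codes(_fixed_repo()))
        assert len(cands) == 1
        assert cands[0].concept_id == "c1"
        assert cands[0].status == "pending"
        assert len(cands[0].occurrences) == 1

    def test_concepts_without_hits_absent(self):
        cands = match(
            [_exp("c1", Code("FAKE-SNOMED", "NOPE")), _exp("c2")],
            index_codes(_fixed_repo()),
        )
        assert cands == []

    def test_planted_fixture_matches_exactly_ground_truth(self):
        spec = fixtures.FixtureSpec(
            seed=1, n_feasibility=20, n_recruitment=0, n_execution=0, frac_matchable=0.6,
            frac_mapped=0.9, frac_structured=0.8,
        )
        bundle = fixtures.generate(spec)
        repo = resolve_inheritance(bundle.concepts)
        cands = pipeline.auto_match(repo, bundle.crosswalk, [bundle.templates])
        assert len(cands) == 12  # 0.6 of 20
        assert {c.concept_id for c in cands} == set(bundle.ground_truth.auto_concepts)

    def test_matchable_fraction_zero_yields_no_candidates(self):
        bundle = fixtures.generate(fixtures.FixtureSpec(seed=2, frac_matchable=0.0))
        repo = resolve_inheritance(bundle.concepts)
        assert pipeline.auto_match(repo, bundle.crosswalk, [bundle.templates]) == []

    def test_matched_concepts_fewer_than_matched_codes(self, elga_bundle):
        """Several codes of one concept may hit; candidates count concepts."""
        repo = resolve_inheritance(elga_bundle.concepts)
        cands = pipeline.auto_match(repo, elga_bundle.crosswalk, [elga_bundle.templates])
        n_codes = len({code for c in cands for code in c.matched_codes()})
        assert len(cands) < n_codes


class TestConsolidate:
    def _occ(self, vs_date, code="L-1"):
        return CodeOccurrence(
            Code("FAKE-LOINC", code), "t-lab", "2021-01-01", "e-code", "valueset", "vs-lab", vs_date
        )

    def test_valueset_versions_collapse_to_latest(self):
        cand = CandidateMatch("c1", frozenset({self._occ("2019-04-01"), self._occ("2021-06-01")}))
        (out,) = consolidate([cand])
        (occ,) = out.occurrences
        assert isinstance(occ, GroupedOccurrence)
        assert occ.valueset_date == "2021-06-01"
        assert occ.codes == (Code("FAKE-LOINC", "L-1"),)

    def test_codes_on_same_valueset_grouped(self):
        occs = {self._occ("2021-06-01", f"L-{i}") for i in range(3)}
        (out,) = consolidate([CandidateMatch("c1", frozenset(occs))])
        (occ,) = out.occurrences
        assert len(occ.codes) == 3

    def test_single_occurrence_unchanged_in_content(self):
        cand = CandidateMatch("c1", frozenset({self._occ("2021-06-01")}))
        (out,) = consolidate([cand])
        (occ,) = out.occurrences
        assert (occ.template_id, occ.element_id, occ.codes) == ("t-lab", "e-code", (Code("FAKE-LOINC", "L-1"),))

    def test_idempotent_and_preserves_candidate_set(self):
        cand = CandidateMatch(
            "c1",
            frozenset({self._occ("2019-04-01"), self._occ("2021-06-01", "L-2"), self._occ("2021-06-01")}),
        )
        once = consolidate([cand])
        twice = consolidate(once)
        assert [c.occurrences for c in once] == [c.occurrences for c in twice]
        assert [c.concept_id for c in once] == ["c1"]


class TestStatusTransitions:
    def test_pending_to_accepted_and_rejected_only(self):
        cand = CandidateMatch("c1", frozenset({CodeOccurrence(Code("FAKE-SNOMED", "F1"), "t", "d", "e", "fixed")}))
        accepted = cand.accept()
        assert accepted.status == "accepted"
        with pytest.raises(ModelError):
            accepted.accept()
        rejected = cand.reject("not equivalent")
        assert rejected.status == "rejected"
        assert rejected.reject_reason == "not equivalent"


class TestToAssociations:
    def test_generic_template_hit_emits_paired_association_with_qualifier(self):
        repo = make_generic_lab_repo()
        cand = CandidateMatch(
            "c1",
            frozenset({CodeOccurrence(Code("FAKE-LOINC", "L-1"), "t-lab", "2021-01-01", "e-code", "valueset", "vs-lab", "2021-06-01")}),
        ).accept()
        (assoc,) = to_associations([cand], [repo])
        assert assoc.element_ids == ("e-code", "e-value")
        assert assoc.qualifier == Code("FAKE-LOINC", "L-1")
        assert assoc.provenance == "automatic"

    def test_rejected_candidate_contributes_nothing(self):
        repo = _fixed_repo()
        cand = CandidateMatch(
            "c1", frozenset({CodeOccurrence(Code("FAKE-SNOMED", "F1"), "t-fix", "2021-01-01", "e1", "fixed")})
        ).reject("wrong")
        assert to_associations([cand], [repo]) == []

    def test_one_concept_two_templates_two_associations(self):
        lab = make_generic_lab_repo()
        fixed = _fixed_repo()
        cand = CandidateMatch(
            "c1",
            frozenset(
                {
                    CodeOccurrence(Code("FAKE-LOINC", "L-1"), "t-lab", "2021-01-01", "e-code", "valueset", "vs-lab", "2021-06-01"),
                    CodeOccurrence(Code("FAKE-SNOMED", "F1"), "t-fix", "2021-01-01", "e1", "fixed"),
                }
            ),
        ).accept()
        assocs = to_associations([cand], [lab, fixed])
        assert len(assocs) == 2
        assert {a.template_id for a in assocs} == {"t-lab", "t-fix"}
        by_template = {a.template_id: a for a in assocs}
        assert by_template["t-lab"].element_ids == ("e-code", "e-value")
        assert by_template["t-fix"].element_ids == ("e1",)
        assert by_template["t-fix"].qualifier is None

    def test_unresolvable_occurrence_is_an_error(self):
        cand = CandidateMatch(
            "c1", frozenset({CodeOccurrence(Code("FAKE-SNOMED", "F1"), "t-gone", "2021-01-01", "e1", "fixed")})
        ).accept()
        with pytest.raises(MatchError, match="t-gone"):
            to_associations([cand], [_fixed_repo()])


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(10))
    def test_match_equals_quadruple_loop_brute_force(self, seed):
        bundle = fixtures.generate(
            fixtures.FixtureSpec(seed=seed, n_feasibility=12, n_recruitment=12,
                                 n_execution=12, n_shared=4)
        )
        repo = resolve_inheritance(bundle.concepts)
        expanded = pipeline.expand_concepts(repo, bundle.crosswalk)
        index = merge_indexes([index_codes(bundle.templates)])
        cands = match(expanded, index)
        brute = brute_force_occurrences(expanded, [bundle.templates])
        assert {c.concept_id: c.occurrences for c in cands} == brute

    def test_planted_precision_and_recall_are_exact(self, elga_bundle):
        """Exact code matching on planted fixtures: matched concepts ==
        ground truth, no false positives, no false negatives."""
        repo = resolve_inheritance(elga_bundle.concepts)
        cands = pipeline.auto_match(repo, elga_bundle.crosswalk, [elga_bundle.templates])
        matched = {c.concept_id for c in cands}
        truth = set(elga_bundle.ground_truth.auto_concepts)
        assert matched == truth
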