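# Methods

## Problem and model

The package answers a structural question about an HL7 CDA-based shared EHR
system: for each data element a clinical trial might need, does the system's
information model provide a place to record it, and is that place structured
(coded, quantity, date/time, boolean) or narrative text?  Three ingredients
are modeled:

* **Concept repository** — datasets of trial data elements for three use
  cases (feasibility checking, patient identification/recruitment, trial
  execution).  Concepts carry a data type, free-text description,
  terminology codes, and a hierarchical group path.  Data elements shared
  between use cases live once in a *basic* dataset and are inherited into
  each use-case dataset; all counting is per use-case instance, so a shared
  element contributes to every use case that includes it.  This is a
  deliberate modeling decision: coverage is a property of a use case, and
  the three use cases are reported (and summed) independently.
* **Template repositories** — template versions keyed by (OID, effective
  date) with elements whose content kind is coded, quantity, datetime,
  boolean or narrative text, and whose terminology binding is absent, a
  fixed code, or a value-set reference (optionally version-pinned).  A
  template is *normative* iff a document type of status "Normative"
  references it; only normative templates describe data structures live in
  the system, so non-normative templates are excluded from matching, and an
  association pointing at one is flagged (warning) and ignored by the
  analyzer rather than treated as coverage.
* **Vocabulary crosswalk** — OMOP-style concept and relationship tables.
  Only the "Maps to" relationship is traversed, exactly one hop from a
  source concept to a standard concept; the expansion then emits every code
  attached to the reached standard concepts, in whatever code system,
  together with the source codes themselves.  Synonym fan-out works through
  shared standard concept keys, never by chaining relationships; edges with
  non-standard targets and other relationship labels are ignored with a
  debug log.  All source codes of a concept are expanded uniformly,
  whichever code system they come from.

## Matching and consolidation

Matching is exact on the canonical (code system, code) pair.  Code-system
identifiers are normalized at parse time through a small OID/alias registry,
so repositories that mix OIDs and short names compare correctly.  No
lexical or display-name matching is attempted: label matching is known to
both miss and fabricate equivalences, and that residue is exactly what the
manual mapping step (hand-authored association files with
`provenance="manual"`) is for.  The scan covers fixed-code bindings and the
value-set contents of a template's direct elements only — codes nested in
referenced sub-templates are out of scope and would need those templates to
be scanned as their own entries.

Raw hits are consolidated before review: occurrences differing only in
value-set effective date collapse to the lexicographically latest version
(ISO-8601 strings are the version keys throughout; a genuine tie is kept
with a warning), and codes hitting the same (template, element, value set)
merge into one grouped occurrence carrying the full code list.
Consolidation is idempotent and never changes which concepts are matched.

A *generic template* is detected when the matched coded element is
value-set bound and a sibling non-narrative, unbound element exists; the
emitted association then spans both elements and carries the matched code
as qualifier (the first such sibling in element order is chosen; if several
codes hit the same element the qualifier is left open with a warning).

## Coverage analysis

Element classification: narrative text → free text; everything else →
structured.  Concept classification: any association touching a structured
element wins; otherwise any association at all means free-text; otherwise
unmapped.  Percentages are integer, rounded half up (`decimal` with
`ROUND_HALF_UP`); an empty denominator yields 0.  Group rows collapse the
group path to its first element.  The report validates its own additivity
(overall = Σ use cases, use case = Σ its groups) before serialization, and
serialization is byte-deterministic (sorted keys, block-style YAML).

## Synthetic studies and what they show

The generator plants, per concept: its dataset(s), group, data type
(derived from a per-group source label + semantic hint through the
normalization rules), final mapping status, whether it carries source
codes, and — for automatically matchable concepts — a complete code path:
source code → crosswalk → standard concept → code present in a template
value set or fixed binding.  Non-matchable concepts receive codes that are
absent from templates (some with inert crosswalk paths, to exercise
expansion without matches), so the matcher's planted precision and recall
are exactly 1 by construction.  Decoys include a non-normative template
carrying a live code and crosswalk edges the loader must ignore.

The ELGA-like preset fixes dataset sizes 75/149/133, a basic dataset of 74
shared elements, 308 of 357 use-case instances carrying source-vocabulary
codes (86%), 58 automatically matchable concepts covering 75 instances
(21%), and every use-case and group row's (concepts, mapped, structured)
triple.  Sharing is arranged so each shared element has one status valid in
every inheriting use case; the preset's counts are structural and therefore
independent of the seed.  Twelve matchable concepts carry a second matching
code, so matched codes outnumber matched concepts, as happens against real
repositories where several codes of one concept hit.

What passing tests do **not** show about real data: the fixtures contain no
lexical ambiguity, no semantically non-equivalent code collisions (the
reason real candidate matches need manual verification), no sub-template
nesting, no multilingual content, and no information about whether
clinicians actually fill the elements in.  The coverage figures measure
recordability, not data availability or completeness.

## Numerical and design choices

* Data-type normalization is total on the declared source labels (Float,
  Integer, Text, String, Date, Boolean); the hint rules map quantity-like
  Float/Integer/Text to Quantity, code-like String/Text/Integer to Code and
  count-like Integer/Float to Count.  Hint-less Float and Integer have no
  literal counterpart in the target enumeration and default to Quantity and
  Count respectively; String defaults to Text.  Unknown labels are rejected
  by name rather than guessed.
* Inheritance resolution copies data type, codes and description from the
  (transitively resolved) source concept, preserves the inheriting
  dataset's own group placement, detects dangling references and cycles by
  name, and is idempotent.  The same concept id appearing in several
  datasets always denotes the same shared concept, which is what lets one
  association classify all its instances consistently.
* Sibling order in the XML dialect carries no meaning; round-trip identity
  is defined on sets of records.  Encoding is fixed to UTF-8.
* Problem sizes in the test suite (fixtures of roughly 10–60 concepts, 200
  randomized studies for the matcher/oracle equivalence, the 357-instance
  preset for end-to-end checks) keep the whole suite in a few seconds while
  exercising every code path; the oracles are naive nested loops kept
  deliberately independent of the indexed implementation.

## Known limitations

Single-hop expansion cannot reach equivalences that real vocabularies
express through chained or lateral relationships.  The XML dialect is a
documented subset of the DECOR exchange format, not a validator for full
exports.  `fetch_project` is a dumb HTTP GET for convenience; everything
else runs offline.  The manual-mapping step is represented only by its
artifacts (association files, candidate review CSV with accept/reject
status) — the judgment itself is out of scope.
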