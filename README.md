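# cdacover

Can a shared electronic health record (EHR) system record the data elements
clinical trials need?  Nation-wide EHR systems built on HL7 CDA (Clinical
Document Architecture) prescribe their content through *templates* — formal
constraint specifications identified by OID and effective date, with
terminology-bound elements.  `cdacover` implements a workflow for measuring
how well such a system's templates cover a repository of trial-relevant
concepts (the data elements commonly needed for trial feasibility checking,
patient identification/recruitment, and trial execution), and for telling
structured coverage apart from free-text coverage.

It is aimed at clinical research informaticians who want to assess, *before*
touching any patient data, whether an EHR infrastructure is structurally
prepared to feed a trial.  It deliberately measures what the information
model *allows* to be recorded, not what clinicians actually fill in.

## The method

1. **Concept repository.** Trial data elements live in DECOR-style datasets,
   one per use case, with data types, hierarchical groups, terminology codes
   (e.g. UMLS-style identifiers), and inheritance from a shared "basic"
   dataset so a data element used by several use cases is defined once but
   counted once per use case.
2. **Code expansion.** Each concept's codes are expanded across code systems
   through an OMOP-style crosswalk: one "Maps to" hop from a source code to
   its standard concept(s), then every code attached to those standard
   concepts is emitted.  No multi-hop closure is attempted.
3. **Automatic matching.** The normative templates of the system's
   building-block repositories (BBRs) are scanned for exact matches between
   expanded codes and fixed-code bindings or bound value-set contents.
   Candidates are consolidated (value-set version duplicates collapsed to the
   latest version, codes hitting the same element grouped) and, after
   validation, emitted as *template associations*.  A hit on a generic
   template (e.g. a laboratory observation specialized by its own `code`
   element) produces a paired association spanning the code and value
   elements, carrying the matched code as qualifier.  Concepts the matcher
   cannot reach are mapped by hand and enter as manual association files.
4. **Coverage analysis.** Per concept and use case: `unmapped`,
   `mapped_free_text`, or `mapped_structured` (a concept reaching both a
   structured and a free-text element counts as structured).  The report —
   per use case, per concept group, and overall, with integer percentages
   rounded half up — is written as YAML
   (schema: `src/cdacover/schemas/coverage_report.schema.json`).

A synthetic-study generator (`cdacover.fixtures`) produces all four inputs
with planted ground truth, including a preset that reproduces the count
structure of a published nation-wide analysis.  All synthetic codes use
reserved fake code systems (`FAKE-UMLS`, `FAKE-LOINC`, ...), so fixtures can
never be mistaken for licensed vocabulary content.

## Worked example

```sh
cdacover fixtures --preset elga --seed 1 --out-dir study/
cdacover match --concepts study/concepts.xml --bbr study/bbr.xml \
    --crosswalk-concepts study/crosswalk_concepts.csv \
    --crosswalk-rels study/crosswalk_relationships.csv \
    --out study/auto.xml --candidates-out study/candidates.csv
cdacover analyze --concepts study/concepts.xml \
    --assoc study/auto.xml --assoc study/manual_associations.xml \
    --bbr study/bbr.xml --out study/report.yaml
```

prints

```
Wrote study inputs to study
Matched 58 concepts (75 use-case instances); wrote 70 associations to study/auto.xml
Overall: 357 concepts, 315 mapped (88%), 275 structured (77%); report at study/report.yaml
```

Reading: of the 357 concept instances across the three use cases (75
feasibility + 149 recruitment + 133 execution; shared concepts counted once
per use case), the automatic code-based matcher alone mapped 58 distinct
concepts covering 75 instances (21%); after merging the manual association
file, 315 instances (88%) can be recorded somewhere in the system's
normative templates and 275 (77%) in structured form.  The YAML report
breaks the same numbers down per use case and per concept group
(laboratory findings, medication, demographics, ...).

The same workflow runs in Python via `cdacover.pipeline.run_coverage`; real
ART-DECOR exports restricted to the documented element subset parse with
`cdacover.decor_io`.

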