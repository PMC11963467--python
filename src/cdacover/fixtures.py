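"""Synthetic-data generator with planted ground truth.

Generates the four inputs of the coverage workflow — a concept repository, a
template (building-block) repository, a vocabulary crosswalk, and a manual
association file — together with a ground-truth record of which concepts the
automatic matcher must find and what each concept's final mapping status is.

Two modes:

* random fixtures, parameterized by :class:`FixtureSpec` (concept counts,
  coded/matchable/structured fractions, group mix, generic-template count);
* an ELGA-like preset whose dataset sizes (75/149/133), code availability
  (308 of 357 concept instances carrying source-vocabulary codes),
  automatically matchable share (75 instances, 21%) and per-group mapping
  statuses reproduce the count structure of a nation-wide CDA-based EHR
  system analysis, down to every use-case and group row.

All synthetic codes use reserved fake code systems ("FAKE-UMLS",
"FAKE-LOINC", ...) so fixtures can never be mistaken for licensed vocabulary
content.  All randomness is confined to this module and derives from the
spec's single integer seed; generation is byte-deterministic.
"""

from __future__ import annotations

import io
import json
import random
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

import pandas as pd

from .analyzer import MappingStatus
from .associations import AssociationDocument, TemplateAssociation
from .model import (
    Code,
    Concept,
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
    normalize_data_type,
)
from .vocab import Crosswalk, load_crosswalk

__all__ = [
    "FixtureSpec",
    "FixtureBundle",
    "GroundTruth",
    "FixtureError",
    "generate",
    "elga_preset",
]


class FixtureError(ValueError):
    """Infeasible or invalid fixture specification."""


BASIC_KEY = "basic"
USE_CASE_KEYS = ("feasibility", "recruitment", "execution")

_DATASET_META = {
    "basic": ("ds-basic", "Basic Data Elements", UseCase.BASIC),
    "feasibility": ("ds-feasibility", "Feasibility checking", UseCase.FEASIBILITY),
    "recruitment": ("ds-recruitment", "Patient identif./recruitment", UseCase.RECRUITMENT),
    "execution": ("ds-execution", "Trial execution", UseCase.EXECUTION),
}

#: group label -> plausible (source data-type label, semantic hint) for
#: deriving each concept's data type through the normalization rules
_GROUP_TYPE = {
    "Demographics": ("String", "code"),
    "Medical history": ("Text", "none"),
    "Diagnosis": ("String", "code"),
    "Procedure": ("String", "code"),
    "Findings": ("Float", "quantity"),
    "Laboratory findings": ("Float", "quantity"),
    "Laboratory": ("Float", "quantity"),
    "Lab data": ("Float", "quantity"),
    "Vital signs": ("Float", "quantity"),
    "Medication": ("String", "code"),
    "Concomitant medication": ("String", "code"),
    "Medical device": ("String", "code"),
    "Scores & classification": ("Integer", "code"),
    "Patient characteristics": ("Integer", "count"),
    "Substance use": ("Integer", "count"),
    "ECG": ("Text", "none"),
    "Adverse events": ("Text", "none"),
    "Disease characteristics": ("String", "code"),
    "Disposition": ("Text", "none"),
    "Patient reported outcome": ("Text", "none"),
    "Surgery": ("String", "code"),
    "Tumor resp.": ("String", "code"),
}

_DEFAULT_GROUP_WEIGHTS = {
    "Laboratory findings": 0.35,
    "Findings": 0.15,
    "Medication": 0.10,
    "Diagnosis": 0.10,
    "Demographics": 0.08,
    "Medical history": 0.08,
    "Vital signs": 0.07,
    "Procedure": 0.04,
    "Substance use": 0.03,
}


def _round_half_up(x: Decimal) -> int:
    return int(x.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


@dataclass
class FixtureSpec:
    """Parameters of a synthetic study.

    The fractions describe the generated population: concepts carrying
    source-vocabulary codes, concepts the automatic matcher must find
    (always a subset of coded, structured-mapped concepts), concepts mapped
    at all, and the structured share of the mapped ones.  ``preset="elga"``
    ignores the numeric knobs and emits the fixed ELGA-like study.
    """

    seed: int = 0
    preset: Optional[str] = None
    n_feasibility: int = 20
    n_recruitment: int = 20
    n_execution: int = 20
    n_shared: int = 0
    frac_coded: float = 0.86
    frac_matchable: float = 0.21
    frac_mapped: float = 0.88
    frac_structured: float = 0.80
    group_weights: dict = field(default_factory=lambda: dict(_DEFAULT_GROUP_WEIGHTS))
    n_generic_templates: int = 1

    def validate(self) -> None:
        for name in ("n_feasibility", "n_recruitment", "n_execution", "n_shared", "n_generic_templates"):
            if getattr(self, name) < 0:
                raise FixtureError(f"{name} must be >= 0")
        for name in ("frac_coded", "frac_matchable", "frac_mapped", "frac_structured"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise FixtureError(f"{name} must be in [0, 1], got {v}")
        if self.frac_matchable > self.frac_coded:
            raise FixtureError(
                "frac_matchable exceeds frac_coded: cannot plant more "
                "automatically matchable concepts than coded ones"
            )
        if self.frac_matchable > self.frac_mapped * self.frac_structured:
            raise FixtureError(
                "frac_matchable exceeds the structured-mapped fraction: "
                "automatic matches always land on structured elements"
            )
        if self.n_generic_templates < 1 and self.frac_matchable > 0:
            raise FixtureError("need at least one generic template to plant matches")


# ---------------------------------------------------------------------------
# planning
# ---------------------------------------------------------------------------


@dataclass
class _Plan:
    idx: int
    group: str
    status: MappingStatus
    datasets: tuple[str, ...]
    coded: bool = True
    auto: bool = False
    extra_code: bool = False
    target: Optional[tuple] = None  # ("generic", g) | ("fixed",)
    manual_generic: Optional[int] = None  # paired manual mapping to generic g
    snomed: bool = False
    name: Optional[str] = None
    target_code: Optional[str] = None

    @property
    def cid(self) -> str:
        return f"c-{self.idx:04d}"

    @property
    def shared(self) -> bool:
        return len(self.datasets) > 1


class _Planner:
    def __init__(self) -> None:
        self.plans: list[_Plan] = []
        self._counter = 0

    def add(self, group: str, status: MappingStatus, datasets, n: int = 1, **kw) -> list[_Plan]:
        out = []
        for _ in range(n):
            self._counter += 1
            p = _Plan(self._counter, group, status, tuple(datasets), **kw)
            self.plans.append(p)
            out.append(p)
        return out


_S = MappingStatus.MAPPED_STRUCTURED
_F = MappingStatus.MAPPED_FREE_TEXT
_U = MappingStatus.UNMAPPED


def _elga_plans() -> list[_Plan]:
    """The fixed ELGA-like study: every group row's (concepts, mapped,
    structured) triple is planted per use case, shared elements live in the
    basic dataset and are inherited where the labels and statuses agree."""
    pl = _Planner()
    FR = ("feasibility", "recruitment")
    FRE = ("feasibility", "recruitment", "execution")

    # --- shared (basic) elements -----------------------------------------
    pl.add("Demographics", _S, FRE, n=2)
    pl.add("Demographics", _S, FR, n=3)
    pl.add("Medical history", _S, FR, n=4)
    pl.add("Medical history", _F, FRE, n=3)
    pl.add("Diagnosis", _S, FR, n=3)
    pl.add("Diagnosis", _U, FR, n=1, coded=False)
    pl.add("Procedure", _F, FR, n=1)
    pl.add("Procedure", _U, FR, n=2, coded=False)
    pl.add("Findings", _S, FR, n=7)
    lab_auto_shared = pl.add(
        "Laboratory findings", _S, FR, n=17, auto=True, target=("generic", 0)
    )
    lab_auto_shared[0].name = "Albumin"
    lab_auto_shared[0].target_code = "1751-7"
    pl.add("Laboratory findings", _S, FR, n=24, manual_generic=0)
    pl.add("Medication", _S, FR, n=7, snomed=True)

    # --- feasibility locals ----------------------------------------------
    pl.add("Medical history", _U, ("feasibility",), n=1, coded=False)

    # --- recruitment locals ----------------------------------------------
    R = ("recruitment",)
    pl.add("Medical history", _U, R, n=3, coded=False)
    pl.add("Medical device", _F, R, n=1)
    pl.add("Diagnosis", _S, R, n=1, snomed=True)
    pl.add("Findings", _S, R, n=9)
    pl.add("Findings", _F, R, n=2)
    pl.add("Findings", _U, R, n=7, coded=False)
    pl.add("Laboratory findings", _S, R, n=20, auto=True, target=("generic", 0))
    pl.add("Laboratory findings", _S, R, n=20, manual_generic=0)
    pl.add("Medication", _S, R, n=1)
    pl.add("Medication", _U, R, n=1, coded=False)
    pl.add("Scores & classification", _F, R, n=9)
    pl.add("Patient characteristics", _S, R, n=1)

    # --- execution locals -------------------------------------------------
    E = ("execution",)
    pl.add("Demographics", _U, E, n=2, coded=False)
    pl.add("ECG", _U, E, n=9, coded=False)
    pl.add("Adverse events", _S, E, n=5)
    pl.add("Adverse events", _U, E, n=6, coded=False)
    pl.add("Medical history", _S, E, n=1)
    pl.add("Disease characteristics", _S, E, n=2)
    pl.add("Disposition", _U, E, n=2, coded=False)
    pl.add("Patient reported outcome", _F, E, n=2, coded=False)
    pl.add("Patient reported outcome", _U, E, n=1, coded=False)
    pl.add("Vital signs", _S, E, n=7, manual_generic=1)
    pl.add("Vital signs", _F, E, n=1)
    pl.add("Laboratory", _S, E, n=21, auto=True, target=("generic", 0))
    pl.add("Laboratory", _S, E, n=36, manual_generic=0)
    pl.add("Lab data", _S, E, n=4)
    pl.add("Lab data", _F, E, n=2)
    pl.add("Concomitant medication", _S, E, n=8, snomed=True)
    pl.add("Concomitant medication", _U, E, n=1, coded=False)
    pl.add("Surgery", _F, E, n=4, coded=False)
    pl.add("Surgery", _U, E, n=1, coded=False)
    pl.add("Substance use", _F, E, n=7)
    pl.add("Substance use", _F, E, n=1, coded=False)
    pl.add("Tumor resp.", _S, E, n=3)
    pl.add("Tumor resp.", _U, E, n=2, coded=False)

    # a second matching code for every fifth auto concept, so matched source
    # codes outnumber matched concepts (several codes can hit per concept)
    autos = [p for p in pl.plans if p.auto]
    for i, p in enumerate(autos):
        if i % 5 == 0:
            p.extra_code = True
    return pl.plans


def _random_plans(spec: FixtureSpec, rng: random.Random) -> list[_Plan]:
    pl = _Planner()
    labels = sorted(spec.group_weights)
    weights = [spec.group_weights[g] for g in labels]
    G = max(spec.n_generic_templates, 1)

    def pick_target() -> tuple:
        if spec.n_generic_templates > 0 and rng.random() < 0.7:
            return ("generic", rng.randrange(spec.n_generic_templates))
        return ("fixed",)

    def add_one(key_tuple, status, auto):
        group = rng.choices(labels, weights=weights, k=1)[0]
        coded = auto or rng.random() < spec.frac_coded
        kw: dict = {"coded": coded, "auto": auto}
        if auto:
            kw["target"] = pick_target()
            if kw["target"][0] == "generic" and rng.random() < 0.25:
                kw["extra_code"] = True
        elif status is _S and spec.n_generic_templates > 0 and rng.random() < 0.3:
            kw["manual_generic"] = rng.randrange(spec.n_generic_templates)
        if rng.random() < 0.15:
            kw["snomed"] = True
        pl.add(group, status, key_tuple, **kw)

    for key, n in zip(USE_CASE_KEYS, (spec.n_feasibility, spec.n_recruitment, spec.n_execution)):
        n_auto = _round_half_up(Decimal(n) * Decimal(str(spec.frac_matchable)))
        n_mapped = _round_half_up(Decimal(n) * Decimal(str(spec.frac_mapped)))
        n_struct = _round_half_up(Decimal(n_mapped) * Decimal(str(spec.frac_structured)))
        n_coded = _round_half_up(Decimal(n) * Decimal(str(spec.frac_coded)))
        if n_auto > n_struct or n_auto > n_coded:
            raise FixtureError(
                f"Dataset {key!r}: {n_auto} matchable concepts but only "
                f"{n_struct} structured / {n_coded} coded available"
            )
        statuses = (
            [(_S, True)] * n_auto
            + [(_S, False)] * (n_struct - n_auto)
            + [(_F, False)] * (n_mapped - n_struct)
            + [(_U, False)] * (n - n_mapped)
        )
        rng.shuffle(statuses)
        for status, auto in statuses:
            add_one((key,), status, auto)

    for _ in range(spec.n_shared):
        n_ds = rng.choice((2, 2, 3))
        keys = tuple(sorted(rng.sample(USE_CASE_KEYS, n_ds), key=USE_CASE_KEYS.index))
        r = rng.random()
        if r < spec.frac_mapped * spec.frac_structured:
            status, auto = _S, rng.random() < spec.frac_matchable
        elif r < spec.frac_mapped:
            status, auto = _F, False
        else:
            status, auto = _U, False
        add_one(keys, status, auto)
    return pl.plans


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Planted expectations: final mapping status per (dataset, concept) and
    the set of concepts the automatic matcher must find."""

    statuses: dict  # dataset id -> {concept id -> MappingStatus value}
    auto_concepts: frozenset

    def expected_counts(self, dataset_id: str) -> tuple[int, int, int]:
        st = self.statuses[dataset_id]
        n = len(st)
        mapped = sum(1 for v in st.values() if v != MappingStatus.UNMAPPED.value)
        structured = sum(1 for v in st.values() if v == MappingStatus.MAPPED_STRUCTURED.value)
        return n, mapped, structured

    def auto_instances(self) -> int:
        """Automatically matchable concept count, once per use case."""
        return sum(
            1
            for st in self.statuses.values()
            for cid in st
            if cid in self.auto_concepts
        )

    def n_instances(self) -> int:
        return sum(len(st) for st in self.statuses.values())

    def to_json(self) -> str:
        return json.dumps(
            {
                "statuses": {ds: dict(sorted(st.items())) for ds, st in sorted(self.statuses.items())},
                "auto_concepts": sorted(self.auto_concepts),
            },
            indent=2,
        )


@dataclass
class FixtureBundle:
    spec: FixtureSpec
    concepts: ConceptRepository
    templates: TemplateRepository
    crosswalk: Crosswalk
    manual_associations: AssociationDocument
    ground_truth: GroundTruth


# ---------------------------------------------------------------------------
# materialization
# ---------------------------------------------------------------------------

_TDATE = "2021-01-01"
_GENERIC_NAMES = {0: "Laboratory Observation", 1: "Vital Signs Observation"}


def _concept_codes(p: _Plan) -> frozenset[Code]:
    codes: set[Code] = set()
    if p.coded:
        prefix = "CU-A" if p.auto else "CU-N"
        codes.add(Code("FAKE-UMLS", f"{prefix}{p.idx:04d}"))
        if p.auto and p.extra_code:
            codes.add(Code("FAKE-UMLS", f"CU-B{p.idx:04d}"))
    if p.snomed:
        codes.add(Code("FAKE-SNOMED", f"S-{p.idx:04d}"))
    return frozenset(codes)


def _target_code(p: _Plan) -> Code:
    if p.target is not None and p.target[0] == "fixed":
        return Code("FAKE-SNOMED", p.target_code or f"F-{p.idx:04d}")
    return Code("FAKE-LOINC", p.target_code or f"L-{p.idx:04d}")


def _build_concept_repo(plans: list[_Plan], project_id: str) -> ConceptRepository:
    basic: list[Concept] = []
    per_ds: dict[str, list[Concept]] = {k: [] for k in USE_CASE_KEYS}
    basic_id = _DATASET_META[BASIC_KEY][0]
    for p in plans:
        label, hint = _GROUP_TYPE.get(p.group, ("Text", "none"))
        data_type = normalize_data_type(label, hint)
        name = p.name or f"{p.group} item {p.idx}"
        full = Concept(
            id=p.cid,
            name=name,
            data_type=data_type,
            group_path=(p.group,),
            description=f"Synthetic trial data element ({p.group.lower()})",
            codes=_concept_codes(p),
        )
        if p.shared:
            basic.append(full)
            for key in p.datasets:
                per_ds[key].append(
                    Concept(
                        id=p.cid,
                        name="",
                        data_type=None,
                        group_path=(p.group,),
                        origin=Inherited(basic_id, p.cid),
                    )
                )
        else:
            per_ds[p.datasets[0]].append(full)

    datasets = []
    if basic:
        ds_id, ds_name, uc = _DATASET_META[BASIC_KEY]
        datasets.append(Dataset(ds_id, ds_name, uc, basic))
    for key in USE_CASE_KEYS:
        ds_id, ds_name, uc = _DATASET_META[key]
        datasets.append(Dataset(ds_id, ds_name, uc, per_ds[key]))
    return ConceptRepository(project_id, datasets)


def _build_templates(plans: list[_Plan], spec: FixtureSpec, repo_id: str) -> TemplateRepository:
    n_generic = spec.n_generic_templates
    generic_codes: dict[int, set[Code]] = {g: set() for g in range(n_generic)}
    fixed_plans: list[_Plan] = []
    for p in plans:
        if not p.auto:
            continue
        if p.target[0] == "generic":
            generic_codes[p.target[1]].add(_target_code(p))
            if p.extra_code:
                generic_codes[p.target[1]].add(Code("FAKE-LOINC", f"L-X{p.idx:04d}"))
        else:
            fixed_plans.append(p)

    templates: list[Template] = []
    value_sets: list[ValueSet] = []
    for g in range(n_generic):
        vs_id = f"vs-gen-{g}"
        codes = generic_codes[g] | {Code("FAKE-LOINC", f"GPLACE-{g}")}
        value_sets.append(ValueSet(vs_id, "2021-06-01", frozenset(codes), name=f"Generic value set {g}"))
        if g == 0:
            # an older version with the same content, to exercise version dedup
            value_sets.append(ValueSet(vs_id, "2019-04-01", frozenset(codes), name=f"Generic value set {g}"))
        templates.append(
            Template(
                template_id=f"1.2.999.11.{g}",
                effective_date=_TDATE,
                name=_GENERIC_NAMES.get(g, f"Generic Observation {g}"),
                elements=(
                    TemplateElement(f"e-code-{g}", "hl7:code", ContentKind.CODED, ValueSetBinding(vs_id)),
                    TemplateElement(f"e-value-{g}", "hl7:value", ContentKind.QUANTITY),
                ),
                normative=True,
            )
        )

    if fixed_plans:
        elements = tuple(
            TemplateElement(f"e-fixed-{p.idx:04d}", "hl7:code", ContentKind.CODED, FixedBinding(_target_code(p)))
            for p in fixed_plans
        )
        templates.append(
            Template("1.2.999.12.0", _TDATE, "Coded Entry", elements, normative=True)
        )

    value_sets.append(
        ValueSet(
            "vs-problem",
            "2020-01-01",
            frozenset(Code("FAKE-ICD10", f"DECOY-{k}") for k in range(5)),
            name="Problem value set",
        )
    )
    templates.append(
        Template(
            "1.2.999.13.0",
            _TDATE,
            "Problem Entry",
            (
                TemplateElement("e-prob-code", "hl7:code", ContentKind.CODED, ValueSetBinding("vs-problem")),
            ),
            normative=True,
        )
    )
    templates.append(
        Template(
            "1.2.999.14.0",
            _TDATE,
            "Lifestyle - uncoded",
            (TemplateElement("e-text", "hl7:text", ContentKind.NARRATIVE_TEXT),),
            normative=True,
        )
    )
    # a draft-only template carrying a live code: must be ignored everywhere
    draft_code = Code("FAKE-LOINC", "GPLACE-0") if n_generic > 0 else Code("FAKE-LOINC", "DRAFT-1")
    auto_generic = [p for p in plans if p.auto and p.target[0] == "generic"]
    if auto_generic:
        draft_code = _target_code(auto_generic[0])
    templates.append(
        Template(
            "1.2.999.15.0",
            _TDATE,
            "Draft Entry",
            (TemplateElement("e-draft-code", "hl7:code", ContentKind.CODED, FixedBinding(draft_code)),),
            normative=False,
        )
    )
    repo = TemplateRepository(repo_id, templates, value_sets)
    repo.validate()
    return repo


def _build_crosswalk(plans: list[_Plan]) -> Crosswalk:
    crows: list[tuple[str, str, str, str]] = []
    rrows: list[tuple[str, str, str]] = []
    for p in plans:
        if p.auto:
            crows.append((f"K{p.idx}s", "FAKE-UMLS", f"CU-A{p.idx:04d}", "false"))
            target = _target_code(p)
            crows.append((f"K{p.idx}t", target.system, target.code, "true"))
            rrows.append((f"K{p.idx}s", f"K{p.idx}t", "Maps to"))
            if p.idx % 6 == 0:
                # synonym on the standard concept, in yet another code system
                crows.append((f"K{p.idx}t", "FAKE-ICD10", f"Y-{p.idx:04d}", "true"))
            if p.extra_code:
                crows.append((f"K{p.idx}x", "FAKE-UMLS", f"CU-B{p.idx:04d}", "false"))
                crows.append((f"K{p.idx}y", "FAKE-LOINC", f"L-X{p.idx:04d}", "true"))
                rrows.append((f"K{p.idx}x", f"K{p.idx}y", "Maps to"))
        elif p.coded and p.idx % 9 == 0:
            # inert path: expands, but the emitted code hits no template
            crows.append((f"K{p.idx}n", "FAKE-UMLS", f"CU-N{p.idx:04d}", "false"))
            crows.append((f"K{p.idx}m", "FAKE-LOINC", f"L-N{p.idx:04d}", "true"))
            rrows.append((f"K{p.idx}n", f"K{p.idx}m", "Maps to"))
    # edges the loader must ignore: non-standard target, non-"Maps to" label
    crows.append(("K-odd1", "FAKE-UMLS", "CU-ODD1", "false"))
    crows.append(("K-odd2", "FAKE-UMLS", "CU-ODD2", "false"))
    rrows.append(("K-odd1", "K-odd2", "Maps to"))
    rrows.append(("K-odd2", "K-odd1", "Subsumes"))

    concept_csv = pd.DataFrame(crows, columns=["concept_key", "system", "code", "standard"]).to_csv(index=False)
    rel_csv = pd.DataFrame(rrows, columns=["source_key", "target_key", "relationship"]).to_csv(index=False)
    return load_crosswalk(io.StringIO(concept_csv), io.StringIO(rel_csv))


def _build_manual_associations(plans: list[_Plan], templates: TemplateRepository, project_id: str) -> AssociationDocument:
    assocs: set[TemplateAssociation] = set()
    first_structured_extra_done = False
    for p in plans:
        if p.auto or p.status is _U:
            continue
        if p.status is _F:
            assocs.add(
                TemplateAssociation(p.cid, "1.2.999.14.0", _TDATE, ("e-text",), provenance="manual")
            )
            continue
        # structured, manually mapped
        if p.manual_generic is not None:
            g = p.manual_generic
            assocs.add(
                TemplateAssociation(
                    p.cid,
                    f"1.2.999.11.{g}",
                    _TDATE,
                    (f"e-code-{g}", f"e-value-{g}"),
                    qualifier=Code("FAKE-LOINC", f"LM-{p.idx:04d}"),
                    provenance="manual",
                )
            )
        else:
            assocs.add(
                TemplateAssociation(p.cid, "1.2.999.13.0", _TDATE, ("e-prob-code",), provenance="manual")
            )
        if not first_structured_extra_done and p.shared:
            # one concept recordable both coded and as free text: the
            # structured target must take precedence in the analysis
            assocs.add(
                TemplateAssociation(p.cid, "1.2.999.14.0", _TDATE, ("e-text",), provenance="manual")
            )
            first_structured_extra_done = True
    return AssociationDocument(project_id, frozenset(assocs))


def _build_ground_truth(plans: list[_Plan]) -> GroundTruth:
    statuses: dict[str, dict[str, str]] = {
        _DATASET_META[k][0]: {} for k in USE_CASE_KEYS
    }
    auto: set[str] = set()
    for p in plans:
        for key in p.datasets:
            statuses[_DATASET_META[key][0]][p.cid] = p.status.value
        if p.auto:
            auto.add(p.cid)
    return GroundTruth(statuses=statuses, auto_concepts=frozenset(auto))


def generate(spec: FixtureSpec) -> FixtureBundle:
    """Generate a complete synthetic study from a spec.

    Deterministic for a given spec (including its seed).  The returned
    concept repository is in as-written form: inherited concepts are stubs
    until :func:`cdacover.model.resolve_inheritance` runs.
    """
    spec.validate()
    rng = random.Random(spec.seed)
    if spec.preset == "elga":
        plans = _elga_plans()
        spec_for_templates = FixtureSpec(
            seed=spec.seed, preset="elga", n_generic_templates=2
        )
    elif spec.preset is None:
        plans = _random_plans(spec, rng)
        spec_for_templates = spec
    else:
        raise FixtureError(f"Unknown preset {spec.preset!r}")

    project = "trial-data-inventory" if spec.preset == "elga" else f"random-inventory-{spec.seed}"
    concepts = _build_concept_repo(plans, project)
    templates = _build_templates(plans, spec_for_templates, f"bbr-{project}")
    crosswalk = _build_crosswalk(plans)
    manual = _build_manual_associations(plans, templates, f"{project}-manual-mappings")
    ground_truth = _build_ground_truth(plans)
    return FixtureBundle(spec, concepts, templates, crosswalk, manual, ground_truth)


def elga_preset(seed: int = 0) -> FixtureSpec:
    """Spec for the fixed ELGA-like study (75/149/133 concepts; 308 of 357
    instances coded; 75 instances = 21% automatically matchable; every
    use-case and group row planted)."""
    return FixtureSpec(seed=seed, preset="elga", n_generic_templates=2)
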