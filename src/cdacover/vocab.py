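"""Cross-terminology code expansion over an OMOP-style vocabulary crosswalk.

The crosswalk consists of a concept table (rows of ``concept_key, system,
code, standard``) and a relationship table (``source_key, target_key,
relationship``).  Expansion follows the standard-concept semantics of the
OHDSI vocabularies: each source code is taken one "Maps to" hop to its
standard concept(s), and every code attached to those standard concepts — in
whatever code system — is emitted, together with the source codes themselves.
There is deliberately no transitive multi-hop closure: synonym fan-out works
by shared standard concept key, not by chaining relationships.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Union

import pandas as pd

from .model import Code, Concept, canonical_system

logger = logging.getLogger(__name__)

__all__ = ["Crosswalk", "ExpandedCodeSet", "CrosswalkError", "load_crosswalk", "expand"]

MAPS_TO = "Maps to"

CONCEPT_COLUMNS = ["concept_key", "system", "code", "standard"]
RELATIONSHIP_COLUMNS = ["source_key", "target_key", "relationship"]


class CrosswalkError(ValueError):
    """Malformed crosswalk tables (duplicates, dangling references)."""


@dataclass
class Crosswalk:
    """Indexed vocabulary tables.

    ``concepts``/``relationships`` keep the raw rows (systems already in
    canonical form); the derived indexes answer the two lookups expansion
    needs: code -> concept keys, and key -> outgoing "Maps to" targets.
    """

    concepts: pd.DataFrame
    relationships: pd.DataFrame
    _keys_by_code: dict[tuple[str, str], tuple[str, ...]] = field(repr=False, default_factory=dict)
    _codes_by_key: dict[str, tuple[Code, ...]] = field(repr=False, default_factory=dict)
    _maps_to: dict[str, tuple[str, ...]] = field(repr=False, default_factory=dict)
    _standard: dict[str, bool] = field(repr=False, default_factory=dict)

    def keys_for(self, code: Code) -> tuple[str, ...]:
        return self._keys_by_code.get((code.system, code.code), ())

    def codes_for(self, concept_key: str) -> tuple[Code, ...]:
        return self._codes_by_key.get(concept_key, ())

    def maps_to(self, concept_key: str) -> tuple[str, ...]:
        return self._maps_to.get(concept_key, ())

    def is_standard(self, concept_key: str) -> bool:
        return self._standard.get(concept_key, False)

    def concept_csv(self) -> str:
        return self.concepts.to_csv(index=False)

    def relationship_csv(self) -> str:
        return self.relationships.to_csv(index=False)


def _as_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    return str(value).strip().lower() in {"true", "1", "t", "yes"}


def load_crosswalk(concept_csv, relationship_csv) -> Crosswalk:
    """Load and index the two crosswalk tables.

    Accepts paths or open file-like objects.  Duplicate ``(system, code)``
    rows and relationships referencing absent concept keys are rejected.
    """
    concepts = pd.read_csv(concept_csv, dtype=str).fillna("")
    relationships = pd.read_csv(relationship_csv, dtype=str).fillna("")
    missing = [c for c in CONCEPT_COLUMNS if c not in concepts.columns]
    if missing:
        raise CrosswalkError(f"Concept table is missing columns {missing}")
    missing = [c for c in RELATIONSHIP_COLUMNS if c not in relationships.columns]
    if missing:
        raise CrosswalkError(f"Relationship table is missing columns {missing}")

    concepts = concepts.copy()
    concepts["system"] = concepts["system"].map(canonical_system)
    concepts["code"] = concepts["code"].str.strip()

    dup = concepts.duplicated(subset=["system", "code"], keep=False)
    if dup.any():
        rows = concepts.loc[dup, ["system", "code"]].drop_duplicates()
        raise CrosswalkError(
            "Duplicate (system, code) rows in concept table: "
            + ", ".join(f"{r.system}:{r.code}" for r in rows.itertuples())
        )

    keys_by_code: dict[tuple[str, str], list[str]] = {}
    codes_by_key: dict[str, list[Code]] = {}
    standard: dict[str, bool] = {}
    for row in concepts.itertuples(index=False):
        key = row.concept_key
        is_std = _as_bool(row.standard)
        if key in standard and standard[key] != is_std:
            raise CrosswalkError(f"Concept key {key!r} has conflicting standard flags")
        standard[key] = is_std
        keys_by_code.setdefault((row.system, row.code), []).append(key)
        codes_by_key.setdefault(key, []).append(Code(row.system, row.code))

    known_keys = set(standard)
    maps_to: dict[str, list[str]] = {}
    for i, row in enumerate(relationships.itertuples(index=False)):
        if row.source_key not in known_keys or row.target_key not in known_keys:
            raise CrosswalkError(
                f"Relationship row {i} ({row.source_key!r} -> {row.target_key!r}) "
                "references a concept key absent from the concept table"
            )
        if row.relationship != MAPS_TO:
            logger.debug("Ignoring non-'Maps to' relationship row %d (%s)", i, row.relationship)
            continue
        if not standard[row.target_key]:
            logger.debug(
                "Ignoring 'Maps to' edge %r -> %r with non-standard target",
                row.source_key,
                row.target_key,
            )
            continue
        maps_to.setdefault(row.source_key, []).append(row.target_key)

    return Crosswalk(
        concepts=concepts,
        relationships=relationships,
        _keys_by_code={k: tuple(sorted(set(v))) for k, v in keys_by_code.items()},
        _codes_by_key={k: tuple(sorted(set(v))) for k, v in codes_by_key.items()},
        _maps_to={k: tuple(sorted(set(v))) for k, v in maps_to.items()},
        _standard=standard,
    )


@dataclass(frozen=True)
class ExpandedCodeSet:
    """A concept's codes expanded across code systems.

    ``trace`` records, for every emitted code, the chain(s) it was reached
    by: ``(source code, standard concept key)`` — the key is ``None`` for a
    source code emitted as itself.
    """

    concept_id: str
    codes: tuple[Code, ...]
    trace: tuple[tuple[Code, tuple[tuple[Code, Optional[str]], ...]], ...] = ()

    def code_set(self) -> frozenset[Code]:
        return frozenset(self.codes)

    def trace_for(self, code: Code) -> tuple[tuple[Code, Optional[str]], ...]:
        for c, chains in self.trace:
            if c == code:
                return chains
        raise KeyError(code)


def expand(concept_or_codes: Union[Concept, "frozenset[Code]", set, tuple, list], crosswalk: Crosswalk, concept_id: Optional[str] = None) -> ExpandedCodeSet:
    """Expand a concept's source codes across code systems.

    For each source code present in the crosswalk, follow "Maps to" to its
    standard concept(s) and emit every code attached to them (the standard
    concepts' own codes included); union with the source codes themselves.
    Source codes absent from the crosswalk contribute only themselves.
    Output ordering is deterministic by (system, code).
    """
    if isinstance(concept_or_codes, Concept):
        source_codes = concept_or_codes.codes
        cid = concept_or_codes.id
    else:
        source_codes = frozenset(concept_or_codes)
        cid = concept_id if concept_id is not None else ""

    chains: dict[Code, set[tuple[Code, Optional[str]]]] = {}
    for src in sorted(source_codes):
        chains.setdefault(src, set()).add((src, None))
        keys = crosswalk.keys_for(src)
        if not keys:
            logger.debug("Code %s:%s absent from crosswalk; emitted as itself", src.system, src.code)
            continue
        for key in keys:
            for std_key in crosswalk.maps_to(key):
                for emitted in crosswalk.codes_for(std_key):
                    chains.setdefault(emitted, set()).add((src, std_key))

    codes = tuple(sorted(chains))
    trace = tuple((c, tuple(sorted(chains[c], key=lambda t: (t[0], t[1] or "")))) for c in codes)
    return ExpandedCodeSet(concept_id=cid, codes=codes, trace=trace)
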