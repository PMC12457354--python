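"""Medical knowledge-graph data model and I/O.

The graph follows a seven-type entity schema (Check, Department, Disease,
Drug, Food, Producer, Symptom) with seven semantic relations such as
``recommend_drug`` (a disease's recommended drug) or ``has_symptom``.
Triples are stored as ``(head-id, relation, tail-id)`` with set semantics;
entity identity during loading is the pair (surface form, type), so the same
surface appearing under two types yields two distinct entities.

The on-disk format is a headerless UTF-8 TSV with five columns::

    head-surface<TAB>head-type<TAB>relation<TAB>tail-surface<TAB>tail-type

carrying entity types inline so a graph file is self-contained.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

ENTITY_TYPES = ("Check", "Department", "Disease", "Drug", "Food", "Producer", "Symptom")
RELATIONS = ("belongs_to", "common_drug", "drugs_of", "need_check",
             "recommend_drug", "has_symptom", "accompany_with")

#: relation -> (allowed head types, allowed tail types)
DEFAULT_SCHEMA: dict[str, tuple[frozenset, frozenset]] = {
    "belongs_to": (frozenset({"Department", "Disease"}), frozenset({"Department"})),
    "common_drug": (frozenset({"Disease"}), frozenset({"Drug"})),
    "drugs_of": (frozenset({"Producer"}), frozenset({"Drug"})),
    "need_check": (frozenset({"Disease"}), frozenset({"Check"})),
    "recommend_drug": (frozenset({"Disease"}), frozenset({"Drug"})),
    "has_symptom": (frozenset({"Disease"}), frozenset({"Symptom"})),
    "accompany_with": (frozenset({"Disease"}), frozenset({"Disease"})),
}


class KGParseError(ValueError):
    pass


class SchemaError(ValueError):
    pass


@dataclass
class KnowledgeGraph:
    """Typed entities, an ordered relation vocabulary, and a triple set."""

    entities: dict[int, tuple[str, str]] = field(default_factory=dict)
    relations: tuple[str, ...] = RELATIONS
    triples: set[tuple[int, str, int]] = field(default_factory=set)
    entity_types: tuple[str, ...] = ENTITY_TYPES

    def __post_init__(self):
        self._by_key: dict[tuple[str, str], int] = {
            (surf, typ): eid for eid, (surf, typ) in self.entities.items()
        }

    @property
    def num_entities(self) -> int:
        return len(self.entities)

    @property
    def num_triples(self) -> int:
        return len(self.triples)

    def add_entity(self, surface: str, entity_type: str, strict: bool = False) -> int:
        if strict and entity_type not in self.entity_types:
            raise SchemaError(f"unknown entity type {entity_type!r}")
        key = (surface, entity_type)
        if key in self._by_key:
            return self._by_key[key]
        eid = len(self.entities)
        self.entities[eid] = key
        self._by_key[key] = eid
        return eid

    def add_triple(self, head: int, relation: str, tail: int) -> None:
        if head not in self.entities or tail not in self.entities:
            raise KGParseError(f"triple references unknown entity id ({head}, {tail})")
        if relation not in self.relations:
            raise SchemaError(f"unknown relation {relation!r}")
        self.triples.add((head, relation, tail))

    def surface(self, eid: int) -> str:
        return self.entities[eid][0]

    def type_of(self, eid: int) -> str:
        return self.entities[eid][1]


def load_triples(path, strict_schema: bool = False,
                 entity_types: tuple[str, ...] = ENTITY_TYPES,
                 relations: tuple[str, ...] = RELATIONS) -> KnowledgeGraph:
    """Load a 5-column triples TSV into a deduplicated KnowledgeGraph.

    Entity ids are assigned by first appearance order, which makes loading
    deterministic for a fixed file.  Under ``strict_schema`` an unknown
    relation or entity type raises :class:`SchemaError`; otherwise unknown
    names are admitted with a warning (advisory mode).
    """
    kg = KnowledgeGraph(entities={}, relations=tuple(relations), triples=set(),
                        entity_types=tuple(entity_types))
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) != 5:
                raise KGParseError(
                    f"{path}:{lineno}: expected 5 tab-separated columns, got {len(cols)}"
                )
            hs, ht, rel, ts, tt = cols
            if rel not in relations:
                if strict_schema:
                    raise SchemaError(f"{path}:{lineno}: unknown relation {rel!r}")
                logger.warning("%s:%d: relation %r outside vocabulary", path, lineno, rel)
                kg.relations = tuple(list(kg.relations) + [rel])
            for typ in (ht, tt):
                if typ not in entity_types:
                    if strict_schema:
                        raise SchemaError(f"{path}:{lineno}: unknown entity type {typ!r}")
                    logger.warning("%s:%d: entity type %r outside vocabulary", path, lineno, typ)
            h = kg.add_entity(hs, ht)
            t = kg.add_entity(ts, tt)
            kg.add_triple(h, rel, t)
    return kg


def save_triples(kg: KnowledgeGraph, path) -> None:
    """Write the graph back as a 5-column TSV (triples in sorted order)."""
    with open(path, "w", encoding="utf-8") as fh:
        for h, rel, t in sorted(kg.triples):
            hs, ht = kg.entities[h]
            ts, tt = kg.entities[t]
            fh.write(f"{hs}\t{ht}\t{rel}\t{ts}\t{tt}\n")


@dataclass
class SurfaceLexicon:
    """Surface-form index used for entity linking by maximum matching."""

    entries: dict[str, tuple[int, str]]
    max_len: int

    def __contains__(self, surface: str) -> bool:
        return surface in self.entries

    def lookup(self, surface: str) -> tuple[int, str] | None:
        return self.entries.get(surface)

    def to_json(self, path) -> None:
        payload = {s: {"id": eid, "type": typ} for s, (eid, typ) in self.entries.items()}
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, ensure_ascii=False, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SurfaceLexicon":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        entries = {s: (v["id"], v["type"]) for s, v in payload.items()}
        max_len = max((len(s) for s in entries), default=0)
        return cls(entries=entries, max_len=max_len)


def build_lexicon(kg: KnowledgeGraph) -> SurfaceLexicon:
    """One lexicon entry per unique surface form.

    On a surface-form collision across entities the entry with the smallest
    entity id wins and the collision is logged (entity disambiguation beyond
    longest match is out of scope).  Empty surfaces are invalid.
    """
    entries: dict[str, tuple[int, str]] = {}
    for eid in sorted(kg.entities):
        surface, typ = kg.entities[eid]
        if not surface:
            raise ValueError(f"entity {eid} has an empty surface form")
        if surface in entries:
            logger.warning(
                "surface collision for %r: keeping entity %d, dropping %d",
                surface, entries[surface][0], eid,
            )
            continue
        entries[surface] = (eid, typ)
    max_len = max((len(s) for s in entries), default=0)
    return SurfaceLexicon(entries=entries, max_len=max_len)


def validate_schema(kg: KnowledgeGraph,
                    schema: dict[str, tuple[frozenset, frozenset]] | None = None
                    ) -> list[tuple[tuple[int, str, int], str]]:
    """Check every triple's head/tail types against the relation schema.

    Returns a list of ``(triple, reason)`` violations; empty means clean.
    A relation present in the graph but absent from the schema is a
    configuration error, not a violation.
    """
    if schema is None:
        schema = DEFAULT_SCHEMA
    used = {rel for _, rel, _ in kg.triples}
    missing = used - set(schema)
    if missing:
        raise SchemaError(f"schema does not cover relations: {sorted(missing)}")
    violations = []
    for triple in sorted(kg.triples):
        h, rel, t = triple
        head_ok, tail_ok = schema[rel]
        htyp, ttyp = kg.type_of(h), kg.type_of(t)
        if htyp not in head_ok:
            violations.append((triple, f"head type {htyp} not allowed for {rel}"))
        if ttyp not in tail_ok:
            violations.append((triple, f"tail type {ttyp} not allowed for {rel}"))
    return violations
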