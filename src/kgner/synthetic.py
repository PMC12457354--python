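"""Seeded generator of a toy medical KG and a matching annotated corpus.

The generator emulates the structure of short Chinese clinical-record
sentences without any restricted data: a closed CJK character alphabet is
partitioned into per-entity-type sub-alphabets (partially overlapping, so
character identity is informative but not trivially separating) plus a
disjoint distractor alphabet for non-entity filler text.  Entity surface
forms (1-6 characters) are sampled per KG type; triples are sampled to
respect the relation schema (e.g. ``has_symptom`` only Disease -> Symptom);
sentences splice entity mentions between distractor runs and carry gold
BIOES labels produced by the span encoder.

A configurable fraction of mentions is "corrupted": replaced by a novel
surface from the same type's alphabet that is absent from the KG, modelling
out-of-vocabulary entities that cannot be linked at fusion time.

Everything is a pure function of (config, seed): fixed seeds give
byte-identical corpus files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kg import DEFAULT_SCHEMA, RELATIONS, KnowledgeGraph, build_lexicon
from .tagging import Span, encode_spans

CJK_BASE = 0x4E00

#: KG entity type -> clinical NER type used for gold labels
DEFAULT_TYPE_MAP = {
    "Disease": "Dis",
    "Drug": "Drug",
    "Symptom": "Anatomy",
    "Check": "LabExam",
    "Department": "Operation",
    "Food": "ImgExam",
    "Producer": "Drug",
}


@dataclass
class SynthConfig:
    entities_per_type: dict = field(default_factory=lambda: {
        "Disease": 30, "Drug": 30, "Symptom": 25, "Check": 25,
        "Department": 12, "Food": 15, "Producer": 10,
    })
    triples_per_relation: dict = field(default_factory=lambda: {
        "recommend_drug": 40, "common_drug": 30, "has_symptom": 40,
        "need_check": 40, "accompany_with": 20, "belongs_to": 12, "drugs_of": 20,
    })
    surface_len_probs: tuple = (0.10, 0.35, 0.30, 0.15, 0.07, 0.03)  # lengths 1..6
    type_alphabet_size: int = 40
    type_alphabet_stride: int = 32     # < size -> neighbouring types overlap
    distractor_alphabet_size: int = 60
    sentences: dict = field(default_factory=lambda: {"train": 800, "dev": 100, "test": 200})
    entities_per_sentence: tuple = ((1, 2, 3), (0.35, 0.45, 0.20))
    distractor_run: tuple[int, int] = (1, 5)   # inclusive range between mentions
    corruption_rate: float = 0.1       # fraction of mentions absent from the KG
    max_sentence_len: int = 510        # encoder max_len - 2
    type_map: dict = field(default_factory=lambda: dict(DEFAULT_TYPE_MAP))
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.corruption_rate <= 1.0:
            raise ValueError("corruption_rate must be in [0, 1]")
        if any(v < 0 for v in self.entities_per_type.values()):
            raise ValueError("entity counts must be nonnegative")


class GenerationError(RuntimeError):
    pass


def _type_alphabet(cfg: SynthConfig, type_idx: int) -> list[str]:
    start = CJK_BASE + type_idx * cfg.type_alphabet_stride
    return [chr(start + i) for i in range(cfg.type_alphabet_size)]


def _distractor_alphabet(cfg: SynthConfig, n_types: int) -> list[str]:
    start = (CJK_BASE + (n_types - 1) * cfg.type_alphabet_stride
             + cfg.type_alphabet_size + 16)
    return [chr(start + i) for i in range(cfg.distractor_alphabet_size)]


def _sample_surface(rng, alphabet, probs) -> str:
    length = 1 + rng.choice(len(probs), p=probs)
    return "".join(rng.choice(alphabet, size=length))


def generate_toy_kg(cfg: SynthConfig) -> KnowledgeGraph:
    """Unique surfaces per type; schema-respecting triples; seed-deterministic."""
    rng = np.random.default_rng(cfg.seed)
    kg = KnowledgeGraph(entities={}, relations=RELATIONS, triples=set())
    by_type: dict[str, list[int]] = {}
    types = sorted(cfg.entities_per_type)
    probs = np.asarray(cfg.surface_len_probs) / np.sum(cfg.surface_len_probs)
    for ti, typ in enumerate(types):
        alphabet = np.array(_type_alphabet(cfg, ti))
        seen: set[str] = set()
        ids = []
        while len(ids) < cfg.entities_per_type[typ]:
            surf = _sample_surface(rng, alphabet, probs)
            if surf in seen:
                continue
            seen.add(surf)
            ids.append(kg.add_entity(surf, typ))
        by_type[typ] = ids
    for rel in RELATIONS:
        want = cfg.triples_per_relation.get(rel, 0)
        heads_ok, tails_ok = DEFAULT_SCHEMA[rel]
        heads = [e for t in sorted(heads_ok) for e in by_type.get(t, [])]
        tails = [e for t in sorted(tails_ok) for e in by_type.get(t, [])]
        possible = len(heads) * len(tails) - (len(set(heads) & set(tails)))
        if want > possible:
            raise GenerationError(
                f"{rel}: requested {want} triples but only {possible} unique pairs exist")
        made = 0
        while made < want:
            h = heads[rng.integers(len(heads))]
            t = tails[rng.integers(len(tails))]
            if h == t or (h, rel, t) in kg.triples:
                continue
            kg.add_triple(h, rel, t)
            made += 1
    return kg


def _novel_surface(rng, alphabet, probs, lexicon_surfaces: set[str]) -> str:
    for _ in range(1000):
        surf = _sample_surface(rng, alphabet, probs)
        if surf not in lexicon_surfaces:
            return surf
    raise GenerationError("could not sample a novel (corrupted) surface")


def generate_corpus(kg: KnowledgeGraph, cfg: SynthConfig
                    ) -> dict[str, list[tuple[str, list[str]]]]:
    """Annotated splits {split: [(text, BIOES labels), ...]}.

    Each sentence alternates distractor runs with entity mentions; gold
    labels come from :func:`encode_spans` over the spliced mention spans, so
    every emitted sequence strict-decodes by construction.
    """
    rng = np.random.default_rng(cfg.seed + 101)
    lex = build_lexicon(kg)
    surfaces_in_kg = set(lex.entries)
    types = sorted(cfg.entities_per_type)
    type_idx = {t: i for i, t in enumerate(types)}
    probs = np.asarray(cfg.surface_len_probs) / np.sum(cfg.surface_len_probs)
    mention_pool = [eid for eid in sorted(kg.entities)
                    if kg.type_of(eid) in cfg.type_map]
    if not mention_pool:
        raise GenerationError("no KG entities map to an NER type")
    distract = np.array(_distractor_alphabet(cfg, len(types)))
    counts, probs_n = cfg.entities_per_sentence
    splits: dict[str, list[tuple[str, list[str]]]] = {}
    self_tally: dict[str, dict[str, int]] = {}
    for split in sorted(cfg.sentences):
        n_sent = cfg.sentences[split]
        sentences = []
        tally: dict[str, int] = {}
        for _ in range(n_sent):
            n_ent = int(rng.choice(counts, p=probs_n))
            chars: list[str] = []
            spans: list[Span] = []
            lo, hi = cfg.distractor_run
            for j in range(n_ent):
                run = rng.integers(lo, hi + 1)
                chars.extend(rng.choice(distract, size=run))
                eid = mention_pool[rng.integers(len(mention_pool))]
                ktype = kg.type_of(eid)
                if rng.random() < cfg.corruption_rate:
                    alphabet = np.array(_type_alphabet(cfg, type_idx[ktype]))
                    surface = _novel_surface(rng, alphabet, probs, surfaces_in_kg)
                else:
                    surface = kg.surface(eid)
                ner_type = cfg.type_map[ktype]
                start = len(chars)
                chars.extend(surface)
                spans.append(Span(start, start + len(surface), ner_type))
                tally[ner_type] = tally.get(ner_type, 0) + 1
            run = rng.integers(lo, hi + 1)
            chars.extend(rng.choice(distract, size=run))
            text = "".join(chars)
            if len(text) > cfg.max_sentence_len:
                raise GenerationError("generated sentence exceeds max length")
            sentences.append((text, encode_spans(len(text), spans)))
        splits[split] = sentences
        self_tally[split] = tally
    splits["_tally"] = self_tally  # internal double-entry record
    return splits


def corpus_stats(splits: dict[str, list[tuple[str, list[str]]]]) -> dict[str, dict[str, int]]:
    """Per-split, per-type gold entity counts (from strict decoding)."""
    from .tagging import decode_labels

    stats: dict[str, dict[str, int]] = {}
    for split, sentences in splits.items():
        if split.startswith("_"):
            continue
        tally: dict[str, int] = {}
        for _, labels in sentences:
            for span in decode_labels(labels, mode="strict"):
                tally[span.entity_type] = tally.get(span.entity_type, 0) + 1
        stats[split] = tally
    return stats


def stats_table(stats: dict[str, dict[str, int]]) -> str:
    types = sorted({t for tally in stats.values() for t in tally})
    splits = sorted(stats)
    lines = ["\t".join(["Entity type"] + splits)]
    for t in types:
        lines.append("\t".join([t] + [str(stats[s].get(t, 0)) for s in splits]))
    return "\n".join(lines)


def planted_kg(n_entities: int = 30, n_relations: int = 3, n_triples: int = 80,
               dim: int = 16, noise: float = 0.05, seed: int = 0
               ) -> tuple[KnowledgeGraph, np.ndarray]:
    """A KG whose triples are exactly consistent with planted translation vectors.

    Entities sit on a translation chain: the planted vector of entity ``k``
    is ``k * u + noise`` for a random direction ``u``, and relation ``j``
    translates by ``(j+1) * u``, so every sampled triple
    ``(k, rel_j, k+j+1)`` satisfies ``h + r = t`` up to the noise.  This is
    the densest exactly-representable structure at these counts: with
    independent relation directions, 30 entities admit at most ~69
    lattice-consistent triples, while hop-multiple relations admit 84.

    Returns the graph and the planted entity vectors (for inspection; TransE
    training starts from its own random init and never sees them).
    """
    rng = np.random.default_rng(seed)
    u = rng.normal(size=dim)
    u *= 0.5 / np.linalg.norm(u)
    planted = (np.arange(n_entities)[:, None] * u[None, :]
               + rng.normal(0.0, noise, size=(n_entities, dim)))
    rels = tuple(f"rel{j}" for j in range(n_relations))
    kg = KnowledgeGraph(entities={}, relations=rels, triples=set(),
                        entity_types=("Concept",))
    for k in range(n_entities):
        kg.add_entity(f"e{k}", "Concept")
    candidates = [(h, rels[j], h + j + 1)
                  for j in range(n_relations)
                  for h in range(n_entities - j - 1)]
    if n_triples > len(candidates):
        raise GenerationError(
            f"requested {n_triples} triples but only {len(candidates)} "
            "lattice-consistent candidates exist")
    for i in rng.permutation(len(candidates))[:n_triples]:
        kg.add_triple(*candidates[i])
    return kg, planted
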