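"""TransE embeddings: scoring, negative sampling, margin loss, training."""

import numpy as np
import pytest

from kgner.kg import KnowledgeGraph
from kgner.transe import (
    KGEmbeddings,
    TransEConfig,
    init_embeddings,
    link_prediction_eval,
    margin_loss,
    sample_negative,
    score_triple,
    train_transe,
)


def chain_kg(n=3):
    kg = KnowledgeGraph(entities={}, relations=("rel",), triples=set(),
                        entity_types=("Concept",))
    ids = [kg.add_entity(f"e{i}", "Concept") for i in range(n)]
    for a, b in zip(ids, ids[1:]):
        kg.add_triple(a, "rel", b)
    return kg


def make_emb(ent, rel, norm_order=2):
    return KGEmbeddings(
        entity_vectors=np.asarray(ent, dtype=float),
        relation_vectors=np.asarray(rel, dtype=float),
        entity_index={i: i for i in range(len(ent))},
        relation_index={"rel": 0},
        dim=len(ent[0]),
        norm_order=norm_order,
    )


def test_init_deterministic_and_normalised():
    kg = chain_kg(10)
    cfg = TransEConfig(dim=16, seed=7)
    a, b = init_embeddings(kg, cfg), init_embeddings(kg, cfg)
    np.testing.assert_array_equal(a.entity_vectors, b.entity_vectors)
    assert a.entity_vectors.shape == (10, 16)
    np.testing.assert_allclose(np.linalg.norm(a.entity_vectors, axis=1), 1.0, atol=1e-6)


def test_score_exact_translation_is_zero():
    emb = make_emb([[1.0, 2.0], [1.5, 2.5]], [[0.5, 0.5]])
    assert score_triple(emb, (0, "rel", 1)) == pytest.approx(0.0)


def test_score_hand_arithmetic_l1_l2():
    ent = [[1.0, 0.0], [0.0, 0.0]]
    rel = [[0.0, 1.0]]
    assert score_triple(make_emb(ent, rel, 1), (0, "rel", 1)) == pytest.approx(2.0)
    assert score_triple(make_emb(ent, rel, 2), (0, "rel", 1)) == pytest.approx(np.sqrt(2))


def test_score_translation_invariance(rng):
    ent = rng.normal(size=(2, 8))
    rel = rng.normal(size=(1, 8))
    shift = rng.normal(size=8)
    a = score_triple(make_emb(ent, rel), (0, "rel", 1))
    b = score_triple(make_emb(ent + shift, rel), (0, "rel", 1))
    assert a == pytest.approx(b, rel=1e-9)


def test_score_triangle_inequality_bound(rng):
    ent = rng.normal(size=(2, 8))
    rel = rng.normal(size=(1, 8))
    emb = make_emb(ent, rel)
    bound = (np.linalg.norm(ent[0]) + np.linalg.norm(rel[0]) + np.linalg.norm(ent[1]))
    assert score_triple(emb, (0, "rel", 1)) <= bound + 1e-9


def test_margin_loss_cases():
    assert margin_loss(0.2, 0.9, gamma=1.0) == pytest.approx(0.3)
    assert margin_loss(0.1, 1.5, gamma=1.0) == 0.0  # clamp when separated
    assert margin_loss(0.7, 0.7, gamma=0.5) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        margin_loss(0.1, 0.2, gamma=0.0)


def test_sample_negative_forced_choice(rng):
    kg = chain_kg(2)
    trip = next(iter(kg.triples))
    for _ in range(20):
        neg = sample_negative(kg, trip, rng)
        changed = [neg[0] != trip[0], neg[2] != trip[2]]
        assert sum(changed) == 1 and neg[1] == trip[1]


def test_sample_negative_head_tail_balance():
    kg = chain_kg(5)
    trip = sorted(kg.triples)[0]
    rng = np.random.default_rng(0)
    head_flips = sum(sample_negative(kg, trip, rng)[0] != trip[0] for _ in range(10000))
    assert abs(head_flips / 10000 - 0.5) < 0.03


def test_train_chain_reduces_positive_score():
    kg = chain_kg(3)
    cfg = TransEConfig(dim=8, epochs=200, lr=0.05, seed=5, batch_size=4)
    emb = train_transe(kg, cfg)
    assert emb.positive_score_trace[-1] < 0.25 * emb.positive_score_trace[0]
    # ball constraint: entity norms never exceed 1
    assert np.linalg.norm(emb.entity_vectors, axis=1).max() <= 1.0 + 1e-6


def test_train_deterministic_trace():
    kg = chain_kg(4)
    cfg = TransEConfig(dim=8, epochs=30, seed=9)
    a, b = train_transe(kg, cfg), train_transe(kg, cfg)
    assert a.loss_trace == b.loss_trace
    np.testing.assert_array_equal(a.entity_vectors, b.entity_vectors)


def test_single_triple_monotone_early_decrease():
    kg = chain_kg(2)
    emb = train_transe(kg, TransEConfig(dim=8, epochs=10, lr=0.01, seed=2, batch_size=1))
    trace = emb.positive_score_trace[:11]
    assert all(b < a + 1e-12 for a, b in zip(trace, trace[1:]))


def test_link_prediction_exact_translations():
    # well-separated entities with exact h + r = t
    ent = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0], [0.0, 5.0]])
    emb = make_emb(ent, [[1.0, 0.0]])
    kg = KnowledgeGraph(entities={i: (f"e{i}", "Concept") for i in range(4)},
                        relations=("rel",), triples={(0, "rel", 1), (1, "rel", 2)},
                        entity_types=("Concept",))
    hits, rank = link_prediction_eval(emb, kg, k=1)
    assert hits == 1.0 and rank == 1.0
    with pytest.raises(ValueError):
        link_prediction_eval(emb, kg, k=0)


def test_link_prediction_random_embeddings_null_rank():
    n = 50
    kg = KnowledgeGraph(entities={i: (f"e{i}", "Concept") for i in range(n)},
                        relations=("rel",), triples=set(), entity_types=("Concept",))
    rng = np.random.default_rng(1)
    for _ in range(40):
        h, t = rng.choice(n, size=2, replace=False)
        kg.triples.add((int(h), "rel", int(t)))
    ranks = []
    for seed in range(5):
        r2 = np.random.default_rng(seed)
        emb = make_emb(r2.normal(size=(n, 8)), r2.normal(size=(1, 8)))
        ranks.append(link_prediction_eval(emb, kg, k=1)[1])
    assert abs(np.mean(ranks) - (n + 1) / 2) < 5  # uniform-rank null


def test_hits_nondecreasing_in_k(rng):
    kg = chain_kg(6)
    emb = train_transe(kg, TransEConfig(dim=8, epochs=50, seed=3))
    hits = [link_prediction_eval(emb, kg, k=k)[0] for k in (1, 2, 3, 5)]
    assert hits == sorted(hits)


def test_checkpoint_roundtrip(tmp_path):
    kg = chain_kg(4)
    emb = train_transe(kg, TransEConfig(dim=8, epochs=5, seed=4))
    emb.save(tmp_path / "kge.npz")
    back = KGEmbeddings.load(tmp_path / "kge.npz")
    np.testing.assert_array_equal(back.entity_vectors, emb.entity_vectors)
    assert back.entity_index == emb.entity_index
    assert back.relation_index == emb.relation_index
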