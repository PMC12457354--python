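"""End-to-end NER model: training behaviour, determinism, prediction contracts."""

import numpy as np
import pytest

from kgner.encoder import EncoderConfig
from kgner.kg import build_lexicon
from kgner.model import NERConfig, NERModel, TrainConfig, split_overlong, train_ner
from kgner.synthetic import SynthConfig, generate_corpus, generate_toy_kg
from kgner.tagging import LabelScheme, decode_labels
from kgner.transe import TransEConfig, train_transe
from kgner.vocab import Vocabulary

TINY_NER = NERConfig(
    encoder=EncoderConfig(layers=1, heads=2, dim=32, ff_dim=64, max_len=64, dropout=0.1),
    kg_dim=16, feature_dim=8, hidden=32, bilstm_layers=1, dropout=0.2,
)


@pytest.fixture(scope="module")
def tiny_world():
    cfg = SynthConfig(seed=21, sentences={"train": 50, "dev": 12, "test": 12})
    kg = generate_toy_kg(cfg)
    lex = build_lexicon(kg)
    emb = train_transe(kg, TransEConfig(dim=16, epochs=30, seed=2))
    splits = generate_corpus(kg, cfg)
    texts = [t for s in ("train", "dev", "test") for t, _ in splits[s]]
    texts.append("".join(lex.entries))
    vocab = Vocabulary.from_texts(texts)
    types = sorted({l.partition("-")[2] for s in ("train", "dev", "test")
                    for _, labs in splits[s] for l in labs if l != "O"})
    return dict(kg=kg, lex=lex, emb=emb, splits=splits, vocab=vocab,
                scheme=LabelScheme(tuple(types)))


def fresh_model(world, seed=0, cfg=TINY_NER):
    model = NERModel(cfg, world["vocab"], world["scheme"],
                     {t: i + 1 for i, t in enumerate(world["kg"].entity_types)},
                     np.random.default_rng(seed))
    model.attach_knowledge(world["emb"], world["lex"])
    return model


@pytest.fixture(scope="module")
def trained(tiny_world):
    model = fresh_model(tiny_world)
    model, trace = train_ner(model, tiny_world["splits"]["train"],
                             tiny_world["splits"]["dev"],
                             TrainConfig(batch_size=8, lr=5e-3, epochs=40, seed=3))
    return model, trace


def test_training_reduces_nll(trained):
    _, trace = trained
    assert trace[19]["train_nll"] < trace[0]["train_nll"]
    assert trace[-1]["train_nll"] < 0.25 * trace[0]["train_nll"]


def test_dev_best_selection(trained):
    _, trace = trained
    best = max(e["dev_f1"] for e in trace)
    assert best >= trace[-1]["dev_f1"]


def test_converged_model_reproduces_training_sentence(tiny_world, trained):
    model, trace = trained
    assert trace[-1]["train_nll"] < 1.0  # converged on the toy task
    hits = 0
    for text, labels in tiny_world["splits"]["train"][:10]:
        gold = decode_labels(labels, mode="strict")
        if model.predict(text) == gold:
            hits += 1
    assert hits >= 7  # overfit sanity: most training sentences reproduced


def test_prediction_contracts(tiny_world, trained):
    model, _ = trained
    assert model.predict("") == []
    for text, _ in tiny_world["splits"]["test"]:
        spans = sorted(model.predict(text))
        for s in spans:
            assert 0 <= s.start < s.end <= len(text)
        for a, b in zip(spans, spans[1:]):
            assert a.end <= b.start  # non-overlapping


def test_training_is_deterministic(tiny_world):
    traces = []
    for _ in range(2):
        model = fresh_model(tiny_world, seed=1)
        _, trace = train_ner(model, tiny_world["splits"]["train"][:16],
                             tiny_world["splits"]["dev"][:4],
                             TrainConfig(batch_size=8, lr=1e-3, epochs=2, seed=5))
        traces.append(trace)
    assert traces[0] == traces[1]


def test_without_kg_arm_changes_only_knowledge_half(tiny_world):
    model = fresh_model(tiny_world, seed=2)
    text = tiny_world["splits"]["test"][0][0]
    with_kg, _ = model.emissions([text], use_kg=True)
    without, _ = model.emissions([text], use_kg=False)
    assert with_kg.shape == without.shape
    assert not np.allclose(with_kg.data, without.data)


def test_joint_width_and_contextual_half(tiny_world):
    """h_joint is exactly [h_bert ; projected knowledge] per character."""
    model = fresh_model(tiny_world, seed=4)
    text = tiny_world["splits"]["test"][0][0]
    batch = model._prepare([text])
    h_all = model.encoder(batch["framed"], mask=batch["attn_mask"])
    h_bert = h_all[:, 1:1 + len(text), :]
    h_joint, _, _ = model.fusion(h_bert, batch["entity_ids"])
    d = model.cfg.encoder.dim
    assert h_joint.shape[-1] == 2 * d
    np.testing.assert_array_equal(h_joint.data[..., :d], h_bert.data)


def test_empty_corpus_raises(tiny_world):
    with pytest.raises(Exception, match="empty"):
        train_ner(fresh_model(tiny_world), [], [], TrainConfig(epochs=1))


def test_run_ablation_pairs_arms_under_shared_seed(tiny_world):
    from kgner.evaluation import run_ablation

    data = tiny_world["splits"]
    result = run_ablation(data["train"][:16], data["dev"][:4], data["test"][:4],
                          lambda seed: fresh_model(tiny_world, seed=seed),
                          TrainConfig(batch_size=8, lr=1e-3, epochs=2, seed=7),
                          seed=7)
    for arm in ("with_kg", "without_kg"):
        assert set(result[arm]["report"].micro) == {"tp", "fp", "fn", "precision",
                                                    "recall", "f1"}
        assert len(result[arm]["trace"]) == 2
    assert set(result["delta"]) == {"precision", "recall", "f1"}


def test_split_overlong():
    assert split_overlong("", 10) == []
    assert split_overlong("abc", 10) == [(0, "abc")]
    text = "aaaa。bbbb。cccc"
    pieces = split_overlong(text, 7)
    assert "".join(p for _, p in pieces) == text
    assert all(len(p) <= 7 for _, p in pieces)
    assert all(text[off:off + len(p)] == p for off, p in pieces)
    # no punctuation at all: hard split
    pieces = split_overlong("x" * 23, 10)
    assert [len(p) for _, p in pieces] == [10, 10, 3]
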