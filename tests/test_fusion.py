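"""Entity linking and contextual/knowledge early fusion."""

import numpy as np
import pytest

from kgner.features import POSITION_IDS, lexicon_position_feature
from kgner.fusion import (
    NONE,
    KnowledgeFusion,
    build_fused_sequence,
    fuse,
    link_entities,
    project_kg,
)
from kgner.nn import Tensor, parameter
from kgner.transe import KGEmbeddings, TransEConfig, init_embeddings


@pytest.fixture
def emb(tiny_kg):
    return init_embeddings(tiny_kg, TransEConfig(dim=8, seed=0))


def test_link_entities_example(tiny_kg, tiny_lexicon):
    ids = link_entities("高血压患者", tiny_lexicon)
    hyp = [eid for eid, (s, _) in tiny_kg.entities.items() if s == "高血压"][0]
    assert list(ids) == [hyp, hyp, hyp, NONE, NONE]


def test_link_entities_empty_lexicon(tiny_kg):
    from kgner.kg import SurfaceLexicon
    lex = SurfaceLexicon(entries={}, max_len=0)
    assert (link_entities("高血压", lex) == NONE).all()


def test_link_regions_coincide_with_position_features(tiny_lexicon):
    text = "高血压患者胸前区痛服卡托普利后"
    linked = link_entities(text, tiny_lexicon) != NONE
    pos = lexicon_position_feature(text, tiny_lexicon) != POSITION_IDS["O"]
    np.testing.assert_array_equal(linked, pos)


def test_project_identity_and_bias(rng):
    w = parameter(np.eye(4))
    b = parameter(np.zeros(4))
    e = rng.normal(size=4).astype(np.float32)
    np.testing.assert_allclose(project_kg(e, w, b).data, e, atol=1e-7)
    b2 = parameter(np.arange(4.0))
    np.testing.assert_allclose(project_kg(np.zeros(4), w, b2).data, np.arange(4.0))


def test_project_linearity(rng):
    w = parameter(rng.normal(size=(4, 3)))
    b = parameter(np.zeros(3))
    e1, e2 = rng.normal(size=4), rng.normal(size=4)
    lhs = project_kg(2.0 * e1 + 3.0 * e2, w, b).data
    rhs = 2.0 * project_kg(e1, w, b).data + 3.0 * project_kg(e2, w, b).data
    np.testing.assert_allclose(lhs, rhs, atol=1e-5)


def test_fuse_is_ordered_concatenation():
    h = Tensor(np.array([1.0, 2.0, 3.0]))
    e = Tensor(np.array([4.0, 5.0, 6.0]))
    np.testing.assert_array_equal(fuse(h, e).data, [1, 2, 3, 4, 5, 6])


def test_fused_sequence_contextual_half_untouched(tiny_kg, tiny_lexicon, emb, rng):
    fusion = KnowledgeFusion(d_model=6, kg_dim=8, rng=rng)
    text = "高血压患者"
    h_bert = Tensor(rng.normal(size=(len(text), 6)).astype(np.float32))
    fs = build_fused_sequence(text, h_bert, emb, tiny_lexicon, fusion)
    assert fs.h_joint.shape == (5, 12)
    np.testing.assert_array_equal(fs.h_joint.data[:, :6], h_bert.data)
    assert list(fs.link_mask) == [True, True, True, False, False]


def test_unlinked_rows_share_placeholder(tiny_kg, tiny_lexicon, emb, rng):
    fusion = KnowledgeFusion(d_model=6, kg_dim=8, rng=rng)
    fusion.set_embeddings(emb)
    text = "平安无事"  # nothing links
    h = Tensor(np.zeros((4, 6), dtype=np.float32))
    fs = build_fused_sequence(text, h, emb, tiny_lexicon, fusion)
    rows = fs.h_joint.data[:, 6:]
    assert np.allclose(rows, rows[0])  # all equal the projected placeholder


def test_zero_mode_toggles_only_unlinked_rows(tiny_kg, tiny_lexicon, emb, rng):
    text = "高血压患者"
    h = Tensor(np.zeros((5, 6), dtype=np.float32))
    out = {}
    for mode in ("placeholder", "zero"):
        fusion = KnowledgeFusion(d_model=6, kg_dim=8,
                                 rng=np.random.default_rng(3), unlinked=mode)
        fusion.set_embeddings(emb)
        out[mode] = build_fused_sequence(text, h, emb, tiny_lexicon, fusion).h_joint.data
    linked = slice(0, 3)
    np.testing.assert_array_equal(out["zero"][linked], out["placeholder"][linked])
    assert not np.allclose(out["zero"][3:], out["placeholder"][3:])


def test_all_characters_linked_to_one_entity_share_knowledge_half(tiny_kg, tiny_lexicon, emb, rng):
    fusion = KnowledgeFusion(d_model=6, kg_dim=8, rng=rng)
    fusion.set_embeddings(emb)
    text = "胸前区"
    h = Tensor(rng.normal(size=(3, 6)).astype(np.float32))
    fs = build_fused_sequence(text, h, emb, tiny_lexicon, fusion)
    rows = fs.h_joint.data[:, 6:]
    assert np.allclose(rows, rows[0])


def test_frozen_entities_receive_no_gradient(tiny_kg, tiny_lexicon, emb, rng):
    fusion = KnowledgeFusion(d_model=6, kg_dim=8, rng=rng, finetune_entities=False)
    fusion.set_embeddings(emb)
    ids = link_entities("高血压患者", tiny_lexicon)
    h = Tensor(np.zeros((1, 5, 6), dtype=np.float32))
    h_joint, _, _ = fusion(h, ids[None, :])
    (h_joint * h_joint).sum().backward()
    assert fusion.proj.W.grad is not None
    assert fusion.proj.b.grad is not None
    assert fusion.placeholder.grad is not None
    assert fusion.entity_matrix.grad is None  # freeze contract


def test_finetune_flag_unfreezes_entities(tiny_kg, tiny_lexicon, emb, rng):
    fusion = KnowledgeFusion(d_model=6, kg_dim=8, rng=rng, finetune_entities=True)
    fusion.set_embeddings(emb)
    ids = link_entities("高血压", tiny_lexicon)
    h = Tensor(np.zeros((1, 3, 6), dtype=np.float32))
    h_joint, _, _ = fusion(h, ids[None, :])
    (h_joint * h_joint).sum().backward()
    assert fusion.entity_matrix.grad is not None


def test_missing_embedding_for_linked_id_raises(tiny_kg, tiny_lexicon, emb, rng):
    fusion = KnowledgeFusion(d_model=6, kg_dim=8, rng=rng)
    emb.entity_index.pop(0)
    fusion.set_embeddings(emb)
    ids = np.zeros(3, dtype=np.int64)  # all linked to entity 0
    with pytest.raises(KeyError):
        fusion.knowledge_rows(ids)
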