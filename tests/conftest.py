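import numpy as np
import pytest

from kgner.kg import KnowledgeGraph, build_lexicon


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_kg():
    """Hand-built KG with the canonical hypertension example triple."""
    kg = KnowledgeGraph(entities={}, triples=set())
    hyp = kg.add_entity("高血压", "Disease")
    cap = kg.add_entity("卡托普利", "Drug")
    chest = kg.add_entity("胸前区", "Symptom")
    dia = kg.add_entity("糖尿病", "Disease")
    kg.add_triple(hyp, "recommend_drug", cap)
    kg.add_triple(hyp, "has_symptom", chest)
    kg.add_triple(dia, "accompany_with", hyp)
    return kg


@pytest.fixture
def tiny_lexicon(tiny_kg):
    return build_lexicon(tiny_kg)
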