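"""Multi-source character features x_i = Concat(p_i, t_i, a_i).

Each character gets three width-``d`` learned embeddings, concatenated in a
fixed order:

* ``p_i`` — a lexicon-derived BIOES position indicator: running forward
  maximum matching against the KG surface lexicon marks matched regions with
  B/I/E (or S for single characters) and everything else O.  This is soft
  evidence, NOT the gold label: it comes only from the input text and the
  lexicon, so the train and inference feature distributions are identical
  and no gold information can leak.
* ``t_i`` — the matched entity's KG type (0 = no match), the contextual
  category feature.
* ``a_i`` — a per-character identity embedding over the character
  vocabulary.

The concatenated vector has width ``3d`` and is appended to the fused
contextual/knowledge representation before the BiLSTM.
"""

from __future__ import annotations

import numpy as np

from .kg import SurfaceLexicon
from .matching import forward_max_match
from .nn import Embedding, Module, concat
from .nn.autodiff import Tensor

#: position-indicator vocabulary for p_i
POSITION_IDS = {"O": 0, "B": 1, "I": 2, "E": 3, "S": 4}


def lexicon_position_feature(text: str, lex: SurfaceLexicon) -> np.ndarray:
    """Per-character B/I/E/S indicator from forward maximum matching (O elsewhere)."""
    ids = np.zeros(len(text), dtype=np.int64)
    for m in forward_max_match(text, lex):
        if m.end - m.start == 1:
            ids[m.start] = POSITION_IDS["S"]
        else:
            ids[m.start] = POSITION_IDS["B"]
            ids[m.start + 1:m.end - 1] = POSITION_IDS["I"]
            ids[m.end - 1] = POSITION_IDS["E"]
    return ids


def context_category_feature(text: str, lex: SurfaceLexicon,
                             type_index: dict[str, int]) -> np.ndarray:
    """Per-character matched-entity-type index; 0 where nothing matched.

    ``type_index`` maps KG entity type names to indices starting at 1.
    """
    ids = np.zeros(len(text), dtype=np.int64)
    for m in forward_max_match(text, lex):
        ids[m.start:m.end] = type_index[m.entity_type]
    return ids


def make_type_index(entity_types) -> dict[str, int]:
    return {t: i + 1 for i, t in enumerate(entity_types)}


class CharFeatures(Module):
    """Learned embedding tables for the three sources plus their assembly."""

    def __init__(self, num_chars: int, num_categories: int, feature_dim: int,
                 rng: np.random.Generator):
        self.feature_dim = feature_dim
        self.position_table = Embedding(len(POSITION_IDS), feature_dim, rng)
        self.category_table = Embedding(num_categories + 1, feature_dim, rng)
        self.char_table = Embedding(num_chars, feature_dim, rng)

    def __call__(self, position_ids: np.ndarray, category_ids: np.ndarray,
                 char_ids: np.ndarray) -> Tensor:
        return assemble_features(position_ids, category_ids, char_ids,
                                 self.position_table, self.category_table,
                                 self.char_table)


def assemble_features(position_ids: np.ndarray, category_ids: np.ndarray,
                      char_ids: np.ndarray, position_table: Embedding,
                      category_table: Embedding, char_table: Embedding) -> Tensor:
    """Look up p, t, a and concatenate per character, in that order (width 3d)."""
    position_ids = np.asarray(position_ids)
    if not (position_ids.shape == np.asarray(category_ids).shape
            == np.asarray(char_ids).shape):
        raise ValueError("feature id sequences must share a shape")
    p = position_table(position_ids)
    t = category_table(np.asarray(category_ids))
    a = char_table(np.asarray(char_ids))
    return concat([p, t, a], axis=-1)
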