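"""Early fusion of contextual vectors with knowledge-graph entity embeddings.

Characters are linked to KG entities by forward maximum matching against the
surface lexicon (the same matcher that drives the character features, so
linked regions and non-O position features coincide).  A linked character
retrieves its entity's TransE vector ``e_i`` (frozen by default); an unlinked
character uses a learned placeholder vector (default) or a zero vector.  The
knowledge vector is mapped into the contextual space by a learned affine
projection and concatenated after the contextual vector:

    e~_i = W_e e_i + b_e
    h_joint_i = [h_i ; e~_i]  in R^{2d}

so the contextual half of the joint representation is never mutated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kg import SurfaceLexicon
from .matching import forward_max_match
from .nn import Linear, Module, Tensor, concat, embedding, parameter, where
from .transe import KGEmbeddings

NONE = -1  # entity id of an unlinked character


def link_entities(text: str, lex: SurfaceLexicon) -> np.ndarray:
    """Per-character entity id from maximum matching; NONE (-1) if unlinked.

    Every character of a matched multi-character span carries the same
    entity id (span-level linking shared across its characters).
    """
    ids = np.full(len(text), NONE, dtype=np.int64)
    for m in forward_max_match(text, lex):
        ids[m.start:m.end] = m.entity_id
    return ids


def project_kg(e: Tensor | np.ndarray, weight: Tensor, bias: Tensor) -> Tensor:
    """Affine projection W_e e + b_e of knowledge vectors into model space."""
    e = e if isinstance(e, Tensor) else Tensor(np.asarray(e, dtype=np.float32))
    return e @ weight + bias


def fuse(h_bert: Tensor, projected: Tensor) -> Tensor:
    """Concatenate (contextual, knowledge) halves along the last axis."""
    return concat([h_bert, projected], axis=-1)


@dataclass
class FusedSequence:
    h_bert: Tensor        # len x d contextual vectors
    kg_vectors: np.ndarray  # len x d' pre-projection knowledge vectors
    h_joint: Tensor       # len x 2d joint representation
    link_mask: np.ndarray  # True where a KG entity was linked


class KnowledgeFusion(Module):
    """Projection parameters, unlinked placeholder, and the fusion forward."""

    def __init__(self, d_model: int, kg_dim: int, rng: np.random.Generator,
                 unlinked: str = "placeholder", finetune_entities: bool = False):
        if unlinked not in ("placeholder", "zero"):
            raise ValueError("unlinked mode must be 'placeholder' or 'zero'")
        self.proj = Linear(kg_dim, d_model, rng)
        self.placeholder = parameter(rng.normal(0.0, 0.02, size=(kg_dim,)))
        self.unlinked = unlinked
        self.kg_dim = kg_dim
        self.finetune_entities = finetune_entities
        self.entity_matrix: Tensor | None = None
        self._row_of: dict[int, int] = {}

    def set_embeddings(self, emb: KGEmbeddings) -> None:
        if emb.dim != self.kg_dim:
            raise ValueError(f"KG embedding dim {emb.dim} != fusion kg_dim {self.kg_dim}")
        self.entity_matrix = Tensor(emb.entity_vectors.astype(np.float32),
                                    requires_grad=self.finetune_entities)
        self._row_of = dict(emb.entity_index)

    def knowledge_rows(self, entity_ids: np.ndarray, use_kg: bool = True) -> tuple[Tensor, np.ndarray]:
        """(len(... ) x d') knowledge vectors and the link mask.

        ``use_kg=False`` is the ablation arm: every position gets the
        unlinked substitute, exactly as if nothing linked.
        """
        entity_ids = np.asarray(entity_ids)
        mask = (entity_ids != NONE) & use_kg
        if mask.any():
            if self.entity_matrix is None:
                raise RuntimeError("set_embeddings() must be called before fusion")
            try:
                rows = np.array([[self._row_of[int(e)] if m else 0
                                  for e, m in zip(row_ids, row_mask)]
                                 for row_ids, row_mask in
                                 zip(np.atleast_2d(entity_ids), np.atleast_2d(mask))])
            except KeyError as exc:
                raise KeyError(f"linked entity id {exc} has no KG embedding") from None
            rows = rows.reshape(entity_ids.shape)
            gathered = embedding(self.entity_matrix, rows)
        else:
            gathered = Tensor(np.zeros(entity_ids.shape + (self.kg_dim,), dtype=np.float32))
        if self.unlinked == "placeholder":
            substitute = self.placeholder
        else:
            substitute = Tensor(np.zeros(self.kg_dim, dtype=np.float32))
        out = where(mask[..., None], gathered, substitute)
        return out, mask

    def __call__(self, h_bert: Tensor, entity_ids: np.ndarray,
                 use_kg: bool = True) -> tuple[Tensor, Tensor, np.ndarray]:
        """Returns (h_joint, raw knowledge rows, link mask)."""
        kg_rows, mask = self.knowledge_rows(entity_ids, use_kg=use_kg)
        projected = self.proj(kg_rows)
        return fuse(h_bert, projected), kg_rows, mask


def build_fused_sequence(text: str, h_bert: Tensor, emb: KGEmbeddings,
                         lex: SurfaceLexicon, fusion: KnowledgeFusion,
                         use_kg: bool = True) -> FusedSequence:
    """Single-sentence convenience wrapper: link, substitute, project, fuse."""
    if fusion.entity_matrix is None:
        fusion.set_embeddings(emb)
    entity_ids = link_entities(text, lex)
    h_joint, kg_rows, mask = fusion(h_bert, entity_ids, use_kg=use_kg)
    return FusedSequence(h_bert=h_bert, kg_vectors=kg_rows.data,
                         h_joint=h_joint, link_mask=mask)
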