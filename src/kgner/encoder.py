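"""Contextual character encoder (transformer, trained from scratch at desk scale).

The input embedding of a framed sequence ``[CLS] c1 ... cn [SEP]`` is the
elementwise sum of token, learned positional, and segment embeddings (all
inputs here are single-segment, so segment id 0 everywhere; the segment
table is kept for checkpoint compatibility with two-segment pretraining).

Each layer applies multi-head scaled dot-product self-attention

    Attention(Q, K, V) = softmax(QK^T / sqrt(d_head)) V

followed by a position-wise feed-forward network, both wrapped in residual
connections and layer normalisation.  Heads attend in separate subspaces and
their outputs are concatenated and mixed by the output matrix ``W_o``.

Large-corpus masked-language-model pretraining is out of scope here: the
encoder trains jointly with the labeler from random initialisation, and
:func:`load_pretrained` is the hook for substituting externally pretrained
weights of compatible shape.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .nn import Embedding, LayerNorm, Linear, Module, Tensor, concat, dropout, softmax


class LengthError(ValueError):
    """Input longer than the encoder's positional table (split upstream)."""


@dataclass
class EncoderConfig:
    layers: int = 2
    heads: int = 2
    dim: int = 64
    ff_dim: int = 128
    max_len: int = 512
    dropout: float = 0.1

    def __post_init__(self):
        if self.dim % self.heads != 0:
            raise ValueError("model dim must be divisible by head count")
        if self.max_len < 2:
            raise ValueError("max_len must leave room for [CLS]/[SEP]")


def scaled_attention(q: Tensor, k: Tensor, v: Tensor,
                     mask: np.ndarray | None = None) -> tuple[Tensor, Tensor]:
    """softmax(QK^T / sqrt(d_head)) V with optional additive padding mask.

    ``mask`` is a boolean array, True at positions that may be attended to;
    masked logits are pushed to -1e9 before the row softmax.  Returns
    (output, attention weights); each weight row is a probability vector.
    """
    d_head = q.shape[-1]
    logits = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(d_head))
    if mask is not None:
        logits = logits + Tensor(np.where(mask, 0.0, -1e9).astype(np.float32))
    weights = softmax(logits, axis=-1)
    return weights @ v, weights


class TransformerLayer(Module):
    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        d = cfg.dim
        self.heads = cfg.heads
        self.wq = Linear(d, d, rng)
        self.wk = Linear(d, d, rng)
        self.wv = Linear(d, d, rng)
        self.wo = Linear(d, d, rng)
        self.ln1 = LayerNorm(d)
        self.ln2 = LayerNorm(d)
        self.ff1 = Linear(d, cfg.ff_dim, rng)
        self.ff2 = Linear(cfg.ff_dim, d, rng)
        self.p_drop = cfg.dropout

    def _split(self, x: Tensor) -> Tensor:
        b, n, d = x.shape
        return x.reshape(b, n, self.heads, d // self.heads).swapaxes(1, 2)

    def multi_head(self, x: Tensor, mask: np.ndarray | None) -> tuple[Tensor, Tensor]:
        """Per-head attention on head-projected inputs, concatenated, then W_o."""
        b, n, d = x.shape
        q, k, v = self._split(self.wq(x)), self._split(self.wk(x)), self._split(self.wv(x))
        attn_mask = None if mask is None else mask[:, None, None, :]
        out, weights = scaled_attention(q, k, v, attn_mask)
        merged = out.swapaxes(1, 2).reshape(b, n, d)
        return self.wo(merged), weights

    def __call__(self, x: Tensor, mask: np.ndarray | None, rng, training: bool) -> Tensor:
        attn, _ = self.multi_head(x, mask)
        x = self.ln1(x + dropout(attn, self.p_drop, rng, training))
        ff = self.ff2(self.ff1(x).relu())
        return self.ln2(x + dropout(ff, self.p_drop, rng, training))


class Encoder(Module):
    def __init__(self, cfg: EncoderConfig, vocab_size: int, rng: np.random.Generator):
        self.cfg = cfg
        self.token_table = Embedding(vocab_size, cfg.dim, rng)
        self.position_table = Embedding(cfg.max_len, cfg.dim, rng)
        self.segment_table = Embedding(2, cfg.dim, rng)
        self.ln_embed = LayerNorm(cfg.dim)
        self.layers = [TransformerLayer(cfg, rng) for _ in range(cfg.layers)]

    def embed_inputs(self, token_ids: np.ndarray,
                     segment_ids: np.ndarray | None = None) -> Tensor:
        """Sum of token + positional + segment embedding lookups."""
        token_ids = np.atleast_2d(token_ids)
        b, n = token_ids.shape
        if n > self.cfg.max_len:
            raise LengthError(f"sequence length {n} exceeds max_len {self.cfg.max_len}")
        positions = np.broadcast_to(np.arange(n), (b, n))
        if segment_ids is None:
            segment_ids = np.zeros_like(token_ids)
        return (self.token_table(token_ids)
                + self.position_table(positions)
                + self.segment_table(segment_ids))

    def __call__(self, token_ids: np.ndarray, mask: np.ndarray | None = None,
                 rng: np.random.Generator | None = None,
                 training: bool = False) -> Tensor:
        """Contextual vectors, one row per input token ([CLS]/[SEP] included)."""
        if training and rng is None:
            raise ValueError("training mode needs an rng for dropout")
        x = self.ln_embed(self.embed_inputs(token_ids))
        x = dropout(x, self.cfg.dropout, rng, training)
        for layer in self.layers:
            x = layer(x, mask, rng, training)
        return x

    # -- checkpointing -------------------------------------------------------
    def save_checkpoint(self, path) -> None:
        state = self.state_dict()
        state["__config__"] = np.frombuffer(
            json.dumps(asdict(self.cfg)).encode(), dtype=np.uint8)
        np.savez(path, **state)


def load_pretrained(path, cfg: EncoderConfig | None = None, vocab_size: int | None = None,
                    strict: bool = True) -> tuple[Encoder, dict]:
    """Build an encoder from a checkpoint; returns (encoder, load report).

    With ``strict`` any shape mismatch raises, naming the first offending
    tensor; otherwise mismatched tensors are skipped and listed in the report.
    """
    with np.load(path) as z:
        state = {k: z[k] for k in z.files if k != "__config__"}
        saved_cfg = EncoderConfig(**json.loads(bytes(z["__config__"]).decode()))
    if cfg is None:
        cfg = saved_cfg
    if vocab_size is None:
        vocab_size = state["token_table.weight"].shape[0]
    enc = Encoder(cfg, vocab_size, np.random.default_rng(0))
    report = enc.load_state_dict(state, strict=strict)
    return enc, report
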