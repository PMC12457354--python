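"""End-to-end NER model: encoder -> knowledge fusion -> features -> BiLSTM -> CRF.

The pipeline per sentence:

1. frame characters as ``[CLS] c1 .. cn [SEP]`` and run the contextual
   encoder; special-token rows are dropped before labelling;
2. link characters to KG entities by lexicon maximum matching and fuse the
   (projected) TransE vectors with the contextual vectors (width 2d);
3. append the multi-source character features x_i = Concat(p_i, t_i, a_i)
   (width 3 * feature_dim; switchable off to recover the pure fused pipeline);
4. a stacked BiLSTM re-contextualises the joint representation;
5. a linear emission layer and a linear-chain CRF score label sequences;
   training minimises the CRF negative log-likelihood end to end (the KG
   entity vectors stay frozen unless fine-tuning is enabled), and prediction
   decodes with Viterbi followed by lenient BIOES span decoding.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field

import numpy as np

from .bilstm import BiLSTM
from .crf import CRF
from .encoder import Encoder, EncoderConfig
from .features import CharFeatures, context_category_feature, lexicon_position_feature
from .fusion import NONE, KnowledgeFusion, link_entities
from .kg import SurfaceLexicon
from .nn import Adam, Linear, Module, Tensor, concat, dropout, no_grad
from .tagging import LabelScheme, Span, decode_labels
from .transe import KGEmbeddings
from .vocab import Vocabulary

SENTENCE_BREAKS = "。；！？"  # 。；！？


class TrainingError(RuntimeError):
    pass


@dataclass
class NERConfig:
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    kg_dim: int = 64
    feature_dim: int = 32
    use_features: bool = True
    unlinked: str = "placeholder"     # substitute for unlinked characters
    finetune_kg: bool = False         # unfreeze TransE entity vectors
    hidden: int = 256                 # BiLSTM hidden size per direction
    bilstm_layers: int = 2
    dropout: float = 0.5
    constrain_decoding: bool = False  # BIOES transition mask in the CRF


@dataclass
class TrainConfig:
    batch_size: int = 16
    lr: float = 1e-4
    epochs: int = 100
    seed: int = 0
    log_path: str | None = None       # optional per-epoch JSONL metrics


def split_overlong(text: str, max_chars: int) -> list[tuple[int, str]]:
    """Cut text into (offset, chunk) pieces of at most ``max_chars`` characters,
    preferring sentence punctuation boundaries; oversized sentence-free runs
    are hard-split."""
    if len(text) <= max_chars:
        return [(0, text)] if text else []
    pieces: list[tuple[int, str]] = []
    start = 0
    while start < len(text):
        window = text[start:start + max_chars]
        if start + len(window) >= len(text):
            cut = len(window)
        else:
            breaks = [i for i, ch in enumerate(window) if ch in SENTENCE_BREAKS]
            cut = breaks[-1] + 1 if breaks else len(window)
        pieces.append((start, text[start:start + cut]))
        start += cut
    return pieces


class NERModel(Module):
    def __init__(self, cfg: NERConfig, vocab: Vocabulary, scheme: LabelScheme,
                 kg_type_index: dict[str, int], rng: np.random.Generator):
        self.cfg = cfg
        self.vocab = vocab
        self.scheme = scheme
        self.kg_type_index = kg_type_index
        self.encoder = Encoder(cfg.encoder, len(vocab), rng)
        self.fusion = KnowledgeFusion(cfg.encoder.dim, cfg.kg_dim, rng,
                                      unlinked=cfg.unlinked,
                                      finetune_entities=cfg.finetune_kg)
        self.features = CharFeatures(len(vocab), len(kg_type_index),
                                     cfg.feature_dim, rng) if cfg.use_features else None
        width = 2 * cfg.encoder.dim + (3 * cfg.feature_dim if cfg.use_features else 0)
        self.bilstm = BiLSTM(width, cfg.hidden, cfg.bilstm_layers, rng,
                             p_drop=cfg.dropout)
        self.emission = Linear(2 * cfg.hidden, len(scheme), rng)
        self.crf = CRF(scheme, rng, constrain=cfg.constrain_decoding)
        self.lexicon: SurfaceLexicon | None = None
        self.default_use_kg = True

    # -- wiring --------------------------------------------------------------
    def attach_knowledge(self, emb: KGEmbeddings, lexicon: SurfaceLexicon) -> None:
        self.fusion.set_embeddings(emb)
        self.lexicon = lexicon

    def _require_lexicon(self) -> SurfaceLexicon:
        if self.lexicon is None:
            raise RuntimeError("attach_knowledge() must be called before use")
        return self.lexicon

    # -- forward -------------------------------------------------------------
    def _prepare(self, texts: list[str]) -> dict:
        lex = self._require_lexicon()
        lengths = np.array([len(t) for t in texts])
        lmax = int(lengths.max())
        framed = np.full((len(texts), lmax + 2), self.vocab.pad_id, dtype=np.int64)
        char_ids = np.full((len(texts), lmax), self.vocab.pad_id, dtype=np.int64)
        entity_ids = np.full((len(texts), lmax), NONE, dtype=np.int64)
        pos_ids = np.zeros((len(texts), lmax), dtype=np.int64)
        cat_ids = np.zeros((len(texts), lmax), dtype=np.int64)
        for i, text in enumerate(texts):
            ids = self.vocab.encode(text)
            framed[i, 0] = self.vocab.cls_id
            framed[i, 1:1 + len(ids)] = ids
            framed[i, 1 + len(ids)] = self.vocab.sep_id
            char_ids[i, :len(ids)] = ids
            entity_ids[i, :len(ids)] = link_entities(text, lex)
            pos_ids[i, :len(ids)] = lexicon_position_feature(text, lex)
            cat_ids[i, :len(ids)] = context_category_feature(text, lex, self.kg_type_index)
        attn_mask = np.arange(lmax + 2)[None, :] < (lengths + 2)[:, None]
        valid = np.arange(lmax)[None, :] < lengths[:, None]
        return dict(framed=framed, char_ids=char_ids, entity_ids=entity_ids,
                    pos_ids=pos_ids, cat_ids=cat_ids, attn_mask=attn_mask,
                    valid=valid, lengths=lengths)

    def emissions(self, texts: list[str], training: bool = False,
                  rng: np.random.Generator | None = None,
                  use_kg: bool | None = None) -> tuple[Tensor, np.ndarray]:
        """Per-character CRF emission scores for a batch of sentences."""
        if use_kg is None:
            use_kg = self.default_use_kg
        batch = self._prepare(texts)
        h_all = self.encoder(batch["framed"], mask=batch["attn_mask"],
                             rng=rng, training=training)
        h_bert = h_all[:, 1:1 + batch["valid"].shape[1], :]  # drop [CLS]/[SEP]
        h_joint, _, _ = self.fusion(h_bert, batch["entity_ids"], use_kg=use_kg)
        if self.features is not None:
            x_feat = self.features(batch["pos_ids"], batch["cat_ids"], batch["char_ids"])
            h_joint = concat([h_joint, x_feat], axis=-1)
        h_seq = self.bilstm(h_joint, batch["valid"], rng=rng, training=training)
        h_seq = dropout(h_seq, self.cfg.dropout, rng, training)
        return self.emission(h_seq), batch["lengths"]

    def loss(self, texts: list[str], label_seqs: list[list[str]],
             rng: np.random.Generator | None = None, training: bool = True,
             use_kg: bool | None = None) -> Tensor:
        emis, lengths = self.emissions(texts, training=training, rng=rng, use_kg=use_kg)
        lmax = int(lengths.max())
        gold = np.zeros((len(texts), lmax), dtype=np.int64)
        for i, labs in enumerate(label_seqs):
            gold[i, :len(labs)] = [self.scheme.index(l) for l in labs]
        return self.crf.nll(emis, gold, lengths)

    # -- inference -----------------------------------------------------------
    def predict_batch(self, texts: list[str], use_kg: bool | None = None,
                      batch_size: int = 32) -> list[list[Span]]:
        out: list[list[Span]] = []
        with no_grad():
            for lo in range(0, len(texts), batch_size):
                chunk = [t for t in texts[lo:lo + batch_size]]
                nonempty = [t for t in chunk if t]
                spans_map: dict[int, list[Span]] = {}
                if nonempty:
                    emis, lengths = self.emissions(nonempty, training=False, use_kg=use_kg)
                    paths = self.crf.decode(emis.data, lengths)
                    decoded = [
                        decode_labels([self.scheme.labels[j] for j in path], mode="lenient")
                        for path in paths
                    ]
                    it = iter(decoded)
                    for i, t in enumerate(chunk):
                        spans_map[i] = next(it) if t else []
                out.extend(spans_map.get(i, []) for i in range(len(chunk)))
        return out

    def predict(self, text: str, use_kg: bool | None = None) -> list[Span]:
        """Spans for one document; overlong text is split at sentence
        punctuation into encoder-sized chunks and the spans re-offset."""
        if not text:
            return []
        pieces = split_overlong(text, self.cfg.encoder.max_len - 2)
        spans: list[Span] = []
        preds = self.predict_batch([p for _, p in pieces], use_kg=use_kg)
        for (offset, _), piece_spans in zip(pieces, preds):
            spans.extend(Span(s.start + offset, s.end + offset, s.entity_type)
                         for s in piece_spans)
        return spans


def labels_to_spans(label_seqs: list[list[str]]) -> list[list[Span]]:
    return [decode_labels(labs, mode="strict") for labs in label_seqs]


def train_ner(model: NERModel, train_data: list[tuple[str, list[str]]],
              dev_data: list[tuple[str, list[str]]], cfg: TrainConfig
              ) -> tuple[NERModel, list[dict]]:
    """Minimise mean CRF NLL with Adam; keep the best-dev-F1 checkpoint.

    ``train_data``/``dev_data`` are (text, BIOES labels) pairs.  Deterministic
    for a fixed seed: shuffling, dropout and initialisation all derive from
    dedicated generators.  Returns the model (restored to its best-dev state)
    and the per-epoch metric trace.
    """
    from .evaluation import per_type_report

    if not train_data:
        raise TrainingError("empty training corpus")
    rng_order = np.random.default_rng(cfg.seed)
    rng_drop = np.random.default_rng(cfg.seed + 1)
    params = model.parameters()
    opt = Adam(params, lr=cfg.lr)
    dev_gold = [decode_labels(labs, mode="strict") for _, labs in dev_data]
    dev_texts = [t for t, _ in dev_data]
    trace: list[dict] = []
    best_f1, best_state = -1.0, None
    for epoch in range(cfg.epochs):
        order = rng_order.permutation(len(train_data))
        total_nll = 0.0
        for lo in range(0, len(order), cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            texts = [train_data[i][0] for i in idx]
            labels = [train_data[i][1] for i in idx]
            opt.zero_grad()
            loss = model.loss(texts, labels, rng=rng_drop, training=True)
            if not np.isfinite(loss.data):
                raise TrainingError(f"NaN/inf loss at epoch {epoch}")
            loss.backward()
            opt.step()
            total_nll += loss.item() * len(idx)
        entry = {"epoch": epoch, "train_nll": total_nll / len(train_data)}
        if dev_data:
            pred = model.predict_batch(dev_texts)
            rep = per_type_report(dev_gold, pred).micro
            entry.update(dev_precision=rep["precision"], dev_recall=rep["recall"],
                         dev_f1=rep["f1"])
            if rep["f1"] > best_f1:
                best_f1 = rep["f1"]
                best_state = copy.deepcopy(model.state_dict())
        trace.append(entry)
        if cfg.log_path:
            with open(cfg.log_path, "a", encoding="utf-8") as fh:
                fh.write(json.dumps(entry) + "\n")
    if best_state is not None:
        model.load_state_dict(best_state)
    return model, trace
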