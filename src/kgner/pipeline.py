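"""End-to-end orchestration: generate -> train KGE -> train NER -> evaluate -> ablate.

Every step is a pure function of (config, seed) and writes its artifacts
under the run output directory together with a verbatim copy of the config,
so any run is reproducible from that directory alone.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from .config import derive_seed, dump_config, load_config
from .encoder import EncoderConfig
from .evaluation import EvalReport, per_type_report
from .kg import KnowledgeGraph, SurfaceLexicon, build_lexicon, load_triples, save_triples
from .model import NERConfig, NERModel, TrainConfig, train_ner
from .synthetic import SynthConfig, corpus_stats, generate_corpus, generate_toy_kg, stats_table
from .tagging import LabelScheme, decode_labels, encode_spans, read_conll, write_conll
from .transe import KGEmbeddings, TransEConfig, train_transe
from .vocab import Vocabulary

logger = logging.getLogger(__name__)


def run_synth(cfg: dict, outdir) -> dict:
    """Generate the toy KG and annotated corpus splits onto disk."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    synth = SynthConfig(**cfg["synth"], seed=derive_seed(cfg["seed"], "synth"))
    kg = generate_toy_kg(synth)
    splits = generate_corpus(kg, synth)
    save_triples(kg, out / "triples.tsv")
    build_lexicon(kg).to_json(out / "lexicon.json")
    for split, sentences in splits.items():
        if split.startswith("_"):
            continue
        write_conll(out / f"{split}.conll", sentences)
    stats = corpus_stats(splits)
    with open(out / "stats.json", "w", encoding="utf-8") as fh:
        json.dump(stats, fh, indent=1, sort_keys=True)
    (out / "stats.txt").write_text(stats_table(stats), encoding="utf-8")
    dump_config(cfg, out / "config.yaml")
    return {"kg": kg, "splits": splits, "stats": stats}


def run_train_kge(cfg: dict, outdir, kg: KnowledgeGraph | None = None) -> KGEmbeddings:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    if kg is None:
        kg = load_triples(out / "triples.tsv")
    tcfg = TransEConfig(**cfg["kge"], seed=derive_seed(cfg["seed"], "kge"))
    emb = train_transe(kg, tcfg)
    emb.save(out / "kge.npz")
    emb.export_tsv(out / "kge.tsv", kg)
    return emb


def build_model(cfg: dict, vocab: Vocabulary, scheme: LabelScheme,
                kg_type_index: dict[str, int], seed: int) -> NERModel:
    ncfg = NERConfig(
        encoder=EncoderConfig(**cfg["encoder"]),
        kg_dim=cfg["kge"]["dim"],
        feature_dim=cfg["features"]["feature_dim"],
        use_features=cfg["features"]["use_features"],
        unlinked=cfg["fusion"]["unlinked"],
        finetune_kg=cfg["fusion"]["finetune_kg"],
        hidden=cfg["labeler"]["hidden"],
        bilstm_layers=cfg["labeler"]["bilstm_layers"],
        dropout=cfg["labeler"]["dropout"],
        constrain_decoding=cfg["labeler"]["constrain_decoding"],
    )
    return NERModel(ncfg, vocab, scheme, kg_type_index,
                    np.random.default_rng(seed))


def _corpus_vocab_scheme(cfg: dict, splits: dict, lexicon: SurfaceLexicon
                         ) -> tuple[Vocabulary, LabelScheme]:
    texts = [t for split, sents in splits.items() if not split.startswith("_")
             for t, _ in sents]
    texts.append("".join(lexicon.entries))
    vocab = Vocabulary.from_texts(texts)
    types = sorted({lab.partition("-")[2]
                    for split, sents in splits.items() if not split.startswith("_")
                    for _t, labs in sents for lab in labs if lab != "O"})
    scheme = LabelScheme(tuple(types))
    return vocab, scheme


def run_train(cfg: dict, outdir, use_kg: bool = True, tag: str = "model") -> dict:
    """Train the NER model on the corpus in `outdir`; write checkpoint + metrics."""
    out = Path(outdir)
    kg = load_triples(out / "triples.tsv")
    lexicon = build_lexicon(kg)
    emb = KGEmbeddings.load(out / "kge.npz")
    splits = {s: read_conll(out / f"{s}.conll") for s in ("train", "dev", "test")}
    vocab, scheme = _corpus_vocab_scheme(cfg, splits, lexicon)
    kg_type_index = {t: i + 1 for i, t in enumerate(kg.entity_types)}
    model = build_model(cfg, vocab, scheme, kg_type_index,
                        derive_seed(cfg["seed"], "ner-init"))
    model.attach_knowledge(emb, lexicon)
    model.default_use_kg = use_kg
    tcfg = TrainConfig(**cfg["training"], seed=derive_seed(cfg["seed"], "ner-train"),
                       log_path=str(out / f"{tag}.metrics.jsonl"))
    model, trace = train_ner(model, splits["train"], splits["dev"], tcfg)
    np.savez(out / f"{tag}.npz", **model.state_dict())
    vocab.save(out / f"{tag}.vocab.txt")
    meta = {"entity_types": list(scheme.entity_types), "use_kg": use_kg,
            "kg_type_index": kg_type_index}
    with open(out / f"{tag}.meta.json", "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
    dump_config(cfg, out / "config.yaml")
    return {"model": model, "trace": trace, "vocab": vocab, "scheme": scheme}


def load_model(cfg: dict, outdir, tag: str = "model") -> NERModel:
    out = Path(outdir)
    kg = load_triples(out / "triples.tsv")
    lexicon = build_lexicon(kg)
    emb = KGEmbeddings.load(out / "kge.npz")
    vocab = Vocabulary.load(out / f"{tag}.vocab.txt")
    with open(out / f"{tag}.meta.json", encoding="utf-8") as fh:
        meta = json.load(fh)
    scheme = LabelScheme(tuple(meta["entity_types"]))
    model = build_model(cfg, vocab, scheme, meta["kg_type_index"],
                        derive_seed(cfg["seed"], "ner-init"))
    model.attach_knowledge(emb, lexicon)
    model.default_use_kg = bool(meta["use_kg"])
    with np.load(out / f"{tag}.npz") as z:
        model.load_state_dict({k: z[k] for k in z.files})
    return model


def run_predict(model: NERModel, texts: list[str]) -> list[dict]:
    """Spans for raw documents, JSON-ready, plus their BIOES projections."""
    results = []
    for text in texts:
        spans = model.predict(text)
        labels = encode_spans(len(text), spans) if text else []
        results.append({
            "text": text,
            "spans": [{"start": s.start, "end": s.end, "type": s.entity_type,
                       "surface": text[s.start:s.end]} for s in spans],
            "labels": labels,
        })
    return results


def run_evaluate(model: NERModel, corpus: list) -> EvalReport:
    gold = [decode_labels(labs, mode="strict") for _, labs in corpus]
    pred = model.predict_batch([t for t, _ in corpus])
    return per_type_report(gold, pred)


def ablation_table(with_kg: EvalReport, without_kg: EvalReport) -> str:
    lines = [f"{'Model':<16}{'P/%':>8}{'R/%':>8}{'F1/%':>8}"]
    for name, rep in (("with KG", with_kg), ("w/o KG", without_kg)):
        m = rep.micro
        lines.append(f"{name:<16}{m['precision']:>8.2f}{m['recall']:>8.2f}{m['f1']:>8.2f}")
    return "\n".join(lines)


def synthetic_benchmark(seed: int = 0, epochs: int = 20,
                        sentences: dict | None = None,
                        lr: float | None = None) -> dict:
    """The package's reference experiment, fully in memory.

    Generates the seeded toy KG + corpus (default 800/100/200 sentences, six
    entity types, 10% out-of-KG mentions), trains TransE, then trains the
    NER model twice under a shared seed — once with linked KG vectors, once
    with the placeholder everywhere (the knowledge ablation) — and reports
    strict entity-level test metrics for both arms.
    """
    from .config import DEFAULTS
    from .tagging import decode_labels

    training = dict(DEFAULTS["training"], epochs=epochs)
    if lr is not None:
        training["lr"] = lr
    cfg = load_config(overrides={"seed": seed, "training": training})
    synth_kw = dict(cfg["synth"])
    if sentences is not None:
        synth_kw["sentences"] = sentences
    synth = SynthConfig(**synth_kw, seed=derive_seed(seed, "synth"))
    kg = generate_toy_kg(synth)
    lexicon = build_lexicon(kg)
    splits = generate_corpus(kg, synth)
    emb = train_transe(kg, TransEConfig(**cfg["kge"], seed=derive_seed(seed, "kge")))
    vocab, scheme = _corpus_vocab_scheme(cfg, splits, lexicon)
    kg_type_index = {t: i + 1 for i, t in enumerate(kg.entity_types)}
    gold = [decode_labels(labs, mode="strict") for _, labs in splits["test"]]
    test_texts = [t for t, _ in splits["test"]]
    out: dict = {"seed": seed, "n_test_sentences": len(test_texts)}
    for arm, use_kg in (("with_kg", True), ("without_kg", False)):
        model = build_model(cfg, vocab, scheme, kg_type_index,
                            derive_seed(seed, "ner-init"))
        model.attach_knowledge(emb, lexicon)
        model.default_use_kg = use_kg
        tcfg = TrainConfig(**cfg["training"], seed=derive_seed(seed, "ner-train"))
        model, trace = train_ner(model, splits["train"], splits["dev"], tcfg)
        pred = model.predict_batch(test_texts)
        out[arm] = {"report": per_type_report(gold, pred), "trace": trace}
    out["delta_f1"] = (out["with_kg"]["report"].f1
                       - out["without_kg"]["report"].f1)
    return out


def run_ablate(cfg: dict, outdir) -> dict:
    """Paired with-KG / without-KG training runs under the shared seed."""
    out = Path(outdir)
    reports = {}
    for arm, use_kg in (("with_kg", True), ("without_kg", False)):
        res = run_train(cfg, out, use_kg=use_kg, tag=arm)
        corpus = read_conll(out / "test.conll")
        reports[arm] = run_evaluate(res["model"], corpus)
    table = ablation_table(reports["with_kg"], reports["without_kg"])
    (out / "ablation.txt").write_text(table, encoding="utf-8")
    payload = {arm: json.loads(rep.to_json()) for arm, rep in reports.items()}
    payload["delta_f1"] = reports["with_kg"].f1 - reports["without_kg"].f1
    with open(out / "ablation.json", "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
    return {"reports": reports, "table": table, "delta_f1": payload["delta_f1"]}
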