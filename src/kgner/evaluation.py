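"""Entity-level precision/recall/F1 (strict match) and the KG ablation harness.

A predicted span counts as a true positive only if an identical
(start, end, type) span exists in the gold annotation of the same sentence —
the strict convention of the CCKS evaluations.  Percentages follow

    P  = TP / (TP + FP) * 100
    R  = TP / (TP + FN) * 100
    F1 = 2 P R / (P + R)

with the zero-denominator convention P = R = F1 = 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .tagging import Span


def _prf(tp: int, fp: int, fn: int) -> dict[str, float]:
    p = 100.0 * tp / (tp + fp) if tp + fp else 0.0
    r = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    f1 = 2.0 * p * r / (p + r) if p + r else 0.0
    return {"tp": tp, "fp": fp, "fn": fn, "precision": p, "recall": r, "f1": f1}


@dataclass
class EvalReport:
    per_type: dict[str, dict[str, float]] = field(default_factory=dict)
    micro: dict[str, float] = field(default_factory=dict)

    @property
    def f1(self) -> float:
        return self.micro["f1"]

    def to_json(self, path=None) -> str:
        payload = json.dumps({"per_type": self.per_type, "micro": self.micro},
                             indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(payload)
        return payload

    def table(self) -> str:
        lines = [f"{'type':<14}{'P/%':>8}{'R/%':>8}{'F1/%':>8}"]
        for typ in sorted(self.per_type):
            c = self.per_type[typ]
            lines.append(f"{typ:<14}{c['precision']:>8.2f}{c['recall']:>8.2f}{c['f1']:>8.2f}")
        m = self.micro
        lines.append(f"{'micro':<14}{m['precision']:>8.2f}{m['recall']:>8.2f}{m['f1']:>8.2f}")
        return "\n".join(lines)


def per_type_report(gold: list, pred: list) -> EvalReport:
    """Strict entity-level report per type plus the pooled micro average.

    ``gold`` and ``pred`` are per-sentence collections of :class:`Span`,
    aligned by index.  A boundary-correct but type-swapped prediction counts
    as a FP for the predicted type and a FN for the gold type.
    """
    if len(gold) != len(pred):
        raise ValueError(f"gold has {len(gold)} sentences, pred has {len(pred)}")
    counts: dict[str, list[int]] = {}

    def bucket(typ):
        return counts.setdefault(typ, [0, 0, 0])  # tp, fp, fn

    for gspans, pspans in zip(gold, pred):
        gset, pset = set(gspans), set(pspans)
        for s in pset & gset:
            bucket(s.entity_type)[0] += 1
        for s in pset - gset:
            bucket(s.entity_type)[1] += 1
        for s in gset - pset:
            bucket(s.entity_type)[2] += 1
    per_type = {typ: _prf(*c) for typ, c in counts.items()}
    tp = sum(c[0] for c in counts.values())
    fp = sum(c[1] for c in counts.values())
    fn = sum(c[2] for c in counts.values())
    return EvalReport(per_type=per_type, micro=_prf(tp, fp, fn))


def entity_prf(gold: list, pred: list) -> EvalReport:
    """Micro-averaged strict-match report (alias over the per-type counting)."""
    return per_type_report(gold, pred)


def run_ablation(train_data, dev_data, test_data, model_factory, train_config,
                 seed: int) -> dict:
    """Train two models identical except the knowledge half of the fusion.

    The with-KG arm uses linked TransE vectors; the without-KG arm replaces
    the knowledge half with the unlinked substitute everywhere.  Both arms
    share the same seed, so the control comparison (KG disabled in both)
    is exactly reproducible.  Returns both reports and their deltas.
    """
    from .model import train_ner  # deferred: avoids a module cycle

    arms = {}
    for arm, use_kg in (("with_kg", True), ("without_kg", False)):
        model = model_factory(seed)
        model.default_use_kg = use_kg
        _, trace = train_ner(model, train_data, dev_data, train_config)
        gold = [s for _, s in _as_spans(test_data)]
        pred = model.predict_batch([t for t, _ in test_data])
        report = per_type_report(gold, pred)
        arms[arm] = {"report": report, "trace": trace}
    with_kg = arms["with_kg"]["report"].micro
    without = arms["without_kg"]["report"].micro
    arms["delta"] = {k: with_kg[k] - without[k] for k in ("precision", "recall", "f1")}
    return arms


def _as_spans(data):
    from .tagging import decode_labels
    return [(text, decode_labels(labels, mode="strict")) for text, labels in data]
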