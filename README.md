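# kgner — knowledge-graph-enhanced clinical NER

`kgner` is a character-level named-entity-recognition library for clinical
text (Chinese electronic medical records in particular), built around one
idea: fuse a contextual character encoder with structured domain knowledge
from a medical knowledge graph, then decode entity spans globally with a
BiLSTM-CRF.  It is aimed at people studying knowledge-enhanced sequence
labelling who need a complete, trainable, dependency-light reference
implementation — every component, from the transformer encoder to the CRF
dynamic programs and the TransE trainer, is implemented on numpy with a
small reverse-mode autodiff engine and is verifiable against brute-force
oracles.

## The model

Characters `c_1..c_n` are framed as `[CLS] c_1 .. c_n [SEP]` and encoded by
a transformer (multi-head scaled dot-product attention,
`softmax(QKᵀ/√d_head)V`, with feed-forward blocks, residual connections and
layer norm) into contextual vectors `h_i ∈ R^d`.

A medical knowledge graph (seven entity types: Check, Department, Disease,
Drug, Food, Producer, Symptom; relations such as `recommend_drug`,
`has_symptom`) is embedded with TransE: a true triple `(h, r, t)` is pushed
toward `h + r ≈ t` by minimising the margin ranking loss
`Σ [γ + f(h,r,t) − f(h',r',t')]₊` with `f = ‖h + r − t‖_p` and corrupted
triples `(h',r',t')`.  Characters are linked to KG entities by forward
maximum matching against the surface lexicon; a linked character retrieves
its (frozen) entity vector `e_i ∈ R^{d'}`, unlinked characters use a learned
placeholder.  The knowledge vector is projected and concatenated:

    ẽ_i = W_e e_i + b_e            h_joint_i = [h_i ; ẽ_i] ∈ R^{2d}

Each character also carries a multi-source feature vector
`x_i = Concat(p_i, t_i, a_i)`: a lexicon-derived BIOES position indicator,
the matched entity's type, and a character-identity embedding.  The
sequence `[h_joint_i ; x_i]` feeds a stacked BiLSTM
(`h_t = [h_t→ ; h_t←]`), a linear emission layer, and a linear-chain CRF
trained by exact negative log-likelihood (forward algorithm in log space)
and decoded with Viterbi.  Spans are read off the BIOES tags
(`B-X I-X* E-X`, `S-X` for single characters).

Because the real clinical benchmarks are access-restricted, the package
ships a seeded synthetic generator that emits a schema-valid toy KG and a
matching annotated corpus (short CJK sentences, six entity types, a
configurable fraction of out-of-KG mentions), so the entire pipeline is
trainable and testable offline.

## A worked example

`examples/04_train_ner.py` trains a deliberately small model on an
80-sentence synthetic corpus (under a minute on one CPU) and prints:

```
dev F1 by epoch 5 / 15 / 30: 32.2 / 81.5 / 81.0 %
text: 伋乗乇乡习乀乆伂伆伅交京伂伆仾企丄丢不企伲伏休伬
gold: [(1, 7, 'Dis'), (10, 12, 'Drug'), (16, 19, 'LabExam')]
pred: [(1, 7, 'Dis'), (10, 12, 'Drug'), (16, 19, 'LabExam')]
```

F1 is strict entity-level (a prediction counts only if boundary and type
both match), in percent; the model reproduces the three gold mentions of
the held-out sentence exactly.  `examples/05_kg_ablation.py` trains twin
models differing only in the knowledge half of the fusion and prints the
paired scores:

```
Model                P/%     R/%    F1/%
with KG            72.37   71.43   71.90
w/o KG             47.13   53.25   50.00

F1 delta (with - without): +21.90 points
```

— at this small data scale the KG vectors carry a large share of the
signal.  The other examples cover BIOES tagging, toy-KG generation with
schema validation, and TransE training/link prediction.

There is also a thin CLI mirroring the pipeline
(`kgner synth | train-kge | train | predict | evaluate | ablate`), each verb
a wrapper over `kgner.pipeline` driven by a YAML config.

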