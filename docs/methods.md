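# Methods

This note documents the modelling choices, parameter defaults, numerical
conventions and known limitations of `kgner`.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Task formulation

Flat character-level NER over a closed set of entity types.  Entities are
non-overlapping half-open character spans `(start, end, type)`; 0-based
coordinates are used everywhere.  Gold and predicted spans are exchanged
with the BIOES tag grammar (`S-X` single, `B-X I-X* E-X` multi-character,
`O` outside).  Nested or overlapping mentions are rejected at encoding —
nesting is a known failure mode of flat BIOES modelling and is out of
scope.  Strict decoding is the exact inverse of encoding and raises on any
sequence no encoding produces; lenient decoding, used on raw model output,
returns the maximal well-formed reading: a dangling `B/I` run is truncated
at its last type-consistent position, a stray `E` becomes a one-character
span, and every non-O position ends up covered.  The lenient decoder is
verified in the tests against a brute-force oracle that enumerates all
non-overlapping sets of supported spans and maximises coverage, then
minimises span count.

## Knowledge graph and linking

The KG uses a seven-type entity schema and seven named relations with a
per-relation type signature (e.g. `recommend_drug: Disease → Drug`,
`has_symptom: Disease → Symptom`).  Entity identity is the pair
(surface form, type); triples are a set.  Schema validation is advisory by
default (violations reported, not fatal) because graph cleaning is assumed
to happen upstream of this package; a strict mode rejects unknown names at
load time.  Entity linking is forward maximum matching of lexicon surfaces
(longest match at each position wins, matched region consumed).  One
matcher implementation backs both linking and the lexicon-derived character
features, so linked regions and non-O position features coincide by
construction.  There is no contextual disambiguation beyond longest match;
surface collisions across entities keep the smallest entity id and are
logged.

## TransE

Scoring is `f(h, r, t) = ‖h + r − t‖_p` with p = 2 by default (p = 1
available); lower is more plausible.  Training minimises the margin
ranking loss `[γ + f(pos) − f(neg)]₊` by minibatch SGD, with corrupted
triples drawn by replacing head or tail (fair coin) with a uniform random
entity; corruptions are unfiltered by default (they may accidentally be
true), with a filtered mode behind a flag.  Defaults: d′ = 64, γ = 1.0,
one negative per positive, lr 0.01.  The KGE optimiser is SGD,
deliberately decoupled from the Adam optimiser of the labeler.

Two numerical choices deserve emphasis:

* **Norm constraint.**  After each epoch entity vectors are projected into
  the unit *ball* (norm clipping), not onto the unit sphere.  Clipping
  still blocks the degenerate solution in which uniform scale inflation
  satisfies every margin, but it leaves the ball's interior available.
  This matters: if every entity has norm exactly 1, the heads and tails of
  a relation `r` must lie on the two disjoint slices `v·r = ∓‖r‖²/2`, so
  at most `num_entities/2` triples per relation can be exactly consistent,
  and translation chains (`h + r = t` repeatedly) are unrepresentable.
  The classic sphere convention remains available
  (`normalization="sphere"`), as does no constraint at all.
* **Learning-rate decay.**  With the L2 distance the hinge gradient is a
  unit vector, so a constant step size leaves positive scores jittering at
  the lr scale.  The lr therefore decays linearly to zero by default
  (`lr_schedule="constant"` to disable).

The parameter-recovery benchmark plants entities on a translation chain:
entity `k` has planted vector `k·u + ε` (‖u‖ = 0.5, ε Gaussian with
σ = 0.05) and relation `j` translates by `(j+1)·u`, so every triple
`(k, rel_j, k+j+1)` is consistent with the planted geometry.  A
consistency argument (entities embed as integer relation-count
coordinates) shows this hop-multiple chain is the densest exactly
representable topology at 30 entities / 3 relations — about 84 candidate
triples versus about 69 for any lattice with independent relation
directions — which is why the benchmark samples 80 triples from it.  The
benchmark's training configuration (γ = 0.05, 20 negatives per positive,
6000 epochs, lr 0.05 decayed) uses a small margin so the hinge stays
active on near neighbours and enough negatives to hit them often.
Evaluation is filtered tail ranking: other true tails for the same
(head, relation) are excluded before ranking.

## Encoder

A standard transformer encoder over characters: token + learned positional
+ segment embeddings summed (single-segment inputs, segment id 0; the
segment table is retained for checkpoint compatibility), then `layers`
blocks of multi-head attention and a feed-forward network with residual
connections and layer norm.  Attention is `softmax(QKᵀ/√d_head)V` with
padding masked at −1e9 before the softmax.  Desk-scale defaults: 2 layers,
2 heads, d = 64, feed-forward 128, max length 512.  Masked-language-model
pretraining is out of scope; the encoder trains jointly with the labeler
from random initialisation, and `load_pretrained` accepts an external
checkpoint of compatible shapes (strict mode errors on the first
mismatched tensor; lenient mode loads what fits and reports the rest).
Inputs longer than max_len − 2 are split at sentence punctuation (。；！？)
into chunks, predicted separately, and re-offset.

## Fusion and character features

Early fusion: the projected knowledge vector is concatenated after the
contextual vector, giving width 2d; the contextual half is never mutated.
Unlinked characters receive a learned placeholder by default — a trainable
"no knowledge" direction optimises better than a hard zero — with the zero
vector behind a flag for ablation.  KG entity vectors are frozen during
NER training unless `finetune_kg` is set; gradients reach the projection
(W_e, b_e) and the placeholder either way.

The multi-source feature vector `x_i = Concat(p_i, t_i, a_i)` (three
learned tables of width d_feat = 32 each) is appended *after* fusion,
giving BiLSTM input width 2d + 3·d_feat; `use_features=False` recovers the
pure fused pipeline.  The position feature is deliberately the *lexicon*
BIOES indicator, not the gold label: gold positions are unavailable at
inference, so feeding them in training would leak labels and split the
train/test feature distributions.  The third source is a character-identity
embedding — the one source that is informative for mentions absent from
the lexicon.

## Labeler

Stacked BiLSTM (default 2 layers, hidden 256 per direction — the
conventional reading of a "hidden size 256" configuration), gates computed
jointly as `[i; o; f; c̃] = [σ; σ; σ; tanh](W[x_t; h_{t−1}] + b)` with
forget-gate bias initialised to 1.  Padded positions carry the previous
state through, so the backward direction cannot leak padding into real
positions, and padded outputs are zeroed.

The CRF is the standard neural linear-chain realisation: the general
weighted-feature-function form collapses to per-position emissions (a
linear map of BiLSTM outputs) plus a learned label-transition matrix, with
explicit learned start/stop vectors for the boundaries.  The partition
function is the forward algorithm in log space (log-sum-exp); training
minimises exact NLL; decoding is Viterbi with ties broken toward the
lowest label index.  BIOES transition constraints (an additive −1e4 mask)
are off by default — transitions are learned, as in standard BiLSTM-CRF
practice — and can be enforced with a flag, in which case decoded
sequences are grammatical by construction.  The oracle equivalence of
forward algorithm and Viterbi with exhaustive enumeration (≤ 6 positions,
≤ 5 labels, 1e-6 relative tolerance) is the module's primary correctness
surface.

Training: Adam, lr 1e-4, batch 16, dropout 0.5 (applied inside the
encoder at its own rate, between BiLSTM layers, and before the emission
layer), up to 100 epochs with the best-dev-F1 checkpoint returned.  All
randomness (init, shuffling, dropout, generation) derives from dedicated
`numpy` generators seeded by a named hash fan-out from one global seed, so
toggling one stage does not reshuffle the others and fixed seeds give
bit-identical runs.

## Synthetic data

The generator emulates the *structure* of short annotated clinical
sentences, not clinical language: a closed CJK alphabet is carved into
per-type sub-alphabets of 40 characters at stride 32 (so neighbouring
types share 20% of their characters — character identity is informative
but not trivially separating) plus a disjoint 60-character distractor
alphabet for filler text.  Surfaces are 1–6 characters (mean ≈ 2.9),
unique per type; triples are sampled to satisfy the relation schema.
Sentences alternate 1–5 distractor characters with 1–3 entity mentions;
gold labels come from the span encoder, so every emitted sequence
strict-decodes.  A corruption rate (default 0.1) replaces that fraction of
mentions with novel same-type surfaces absent from the KG, modelling
out-of-vocabulary entities that cannot be linked; raising it lowers the
achievable linking rate monotonically.  CJK characters are used
deliberately so multi-byte text handling is exercised end to end.

What passing the synthetic benchmark shows: the pipeline can learn to
combine lexicon evidence, character identity and KG vectors into exact
span predictions, and the knowledge half carries real signal (the ablation
gap).  What it does not show: robustness to real clinical language —
abbreviations, nesting, segmentation ambiguity, annotation noise — none of
which the generator models.

## Benchmark problem sizes

The reference experiment uses 800/100/200 train/dev/test sentences, the
default toy KG (147 entities, 202 triples), TransE at d′ = 64, the
2-layer d = 64 encoder, and 20 training epochs — sizes chosen so the full
benchmark (both ablation arms) completes in roughly 10 minutes on one CPU
while leaving a wide margin over its F1 threshold.  The smaller examples
in `examples/` shrink the corpus and model further and raise the learning
rate accordingly.

## Known limitations

* No subword/WordPiece tokenisation; the character vocabulary is the unit.
* Longest-match linking cannot disambiguate colliding surfaces.
* The margin objective optimises ranking, not calibrated probabilities;
  TransE scores are comparable only within one trained model.
* The autodiff engine is minimal by design (float32, no fused kernels);
  it is adequate for desk-scale models, not GPU-scale training.
* With `constrain_decoding` off the raw Viterbi path can be ungrammatical;
  the lenient decoder then applies its documented truncation reading.
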