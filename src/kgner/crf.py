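"""Linear-chain CRF: path scoring, partition function, NLL, Viterbi.

The general feature-function CRF

    P(Y|X) = exp( sum_i sum_j w_j f_j(x_i, y_{i-1}, y_i) ) / Z(X)

is realised in its standard neural form: the feature functions collapse to
(i) per-position emission scores (a learned linear map of the BiLSTM output)
and (ii) a learned label-transition matrix, plus explicit start/stop
transition vectors for the sequence boundaries.  ``Z(X)`` is computed by the
forward algorithm in log space (log-sum-exp), training minimises
``log Z - score(gold)``, and decoding uses the Viterbi dynamic program with
ties broken toward the lowest label index.

Optionally a BIOES constraint mask pushes grammatically impossible
transitions (e.g. ``B-X -> O``) to an effectively -inf score, so decoded
sequences are always well-formed.
"""

from __future__ import annotations

import numpy as np

from .nn import Module, Tensor, logsumexp, parameter, where
from .tagging import LabelScheme, is_valid_transition, valid_end, valid_start

NEG_INF = -1e4  # additive penalty standing in for -infinity (log-space safe)


# -- single-sequence numpy reference operations ------------------------------

def crf_path_score(emissions: np.ndarray, transitions: np.ndarray,
                   y: list[int] | np.ndarray,
                   start: np.ndarray | None = None,
                   stop: np.ndarray | None = None) -> float:
    """Unnormalised log-score of one label path."""
    emissions = np.asarray(emissions, dtype=np.float64)
    n, k = emissions.shape
    y = list(y)
    if len(y) != n:
        raise ValueError("label path length must match emissions")
    if any(not 0 <= lab < k for lab in y):
        raise ValueError("label index out of vocabulary")
    start = np.zeros(k) if start is None else start
    stop = np.zeros(k) if stop is None else stop
    score = float(start[y[0]]) + float(stop[y[-1]])
    score += float(emissions[np.arange(n), y].sum())
    score += float(np.asarray(transitions, dtype=np.float64)[y[:-1], y[1:]].sum())
    return score


def crf_log_partition(emissions: np.ndarray, transitions: np.ndarray,
                      start: np.ndarray | None = None,
                      stop: np.ndarray | None = None) -> float:
    """log Z(X) by the forward algorithm in log space."""
    emissions = np.asarray(emissions, dtype=np.float64)
    transitions = np.asarray(transitions, dtype=np.float64)
    n, k = emissions.shape
    start = np.zeros(k) if start is None else start
    stop = np.zeros(k) if stop is None else stop
    alpha = start + emissions[0]
    for t in range(1, n):
        scores = alpha[:, None] + transitions + emissions[t][None, :]
        m = scores.max(axis=0)
        alpha = m + np.log(np.exp(scores - m[None, :]).sum(axis=0))
    alpha = alpha + stop
    m = alpha.max()
    return float(m + np.log(np.exp(alpha - m).sum()))


def crf_nll(emissions: np.ndarray, transitions: np.ndarray, y,
            start: np.ndarray | None = None, stop: np.ndarray | None = None) -> float:
    """-log P(Y|X) = log Z - path score; nonnegative."""
    return (crf_log_partition(emissions, transitions, start, stop)
            - crf_path_score(emissions, transitions, y, start, stop))


def viterbi_decode(emissions: np.ndarray, transitions: np.ndarray,
                   start: np.ndarray | None = None,
                   stop: np.ndarray | None = None) -> tuple[list[int], float]:
    """Best-scoring label path and its score (argmax ties -> lowest index)."""
    emissions = np.asarray(emissions, dtype=np.float64)
    transitions = np.asarray(transitions, dtype=np.float64)
    n, k = emissions.shape
    start = np.zeros(k) if start is None else start
    stop = np.zeros(k) if stop is None else stop
    delta = start + emissions[0]
    back = np.zeros((n, k), dtype=np.int64)
    for t in range(1, n):
        scores = delta[:, None] + transitions  # (prev, next)
        back[t] = scores.argmax(axis=0)  # first max = lowest prev index
        delta = scores.max(axis=0) + emissions[t]
    final = delta + stop
    last = int(final.argmax())
    best = float(final[last])
    path = [last]
    for t in range(n - 1, 0, -1):
        path.append(int(back[t, path[-1]]))
    return path[::-1], best


# -- trainable module with batched log-likelihood ----------------------------

def bioes_constraint_masks(scheme: LabelScheme) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Additive masks (transition, start, stop): 0 if allowed, NEG_INF if not."""
    labs = scheme.labels
    k = len(labs)
    trans = np.full((k, k), NEG_INF, dtype=np.float32)
    for i, a in enumerate(labs):
        for j, b in enumerate(labs):
            if is_valid_transition(a, b):
                trans[i, j] = 0.0
    start = np.array([0.0 if valid_start(l) else NEG_INF for l in labs], dtype=np.float32)
    stop = np.array([0.0 if valid_end(l) else NEG_INF for l in labs], dtype=np.float32)
    return trans, start, stop


class CRF(Module):
    def __init__(self, scheme: LabelScheme, rng: np.random.Generator,
                 constrain: bool = False):
        k = len(scheme)
        self.scheme = scheme
        self.transitions = parameter(rng.normal(0.0, 0.01, size=(k, k)))
        self.start = parameter(np.zeros(k))
        self.stop = parameter(np.zeros(k))
        self.constrain = constrain
        self._masks = bioes_constraint_masks(scheme)

    def effective(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Numpy transition/start/stop with the constraint mask applied."""
        t, s, e = self.transitions.data, self.start.data, self.stop.data
        if self.constrain:
            mt, ms, me = self._masks
            return t + mt, s + ms, e + me
        return t, s, e

    def nll(self, emissions: Tensor, gold: np.ndarray, lengths: np.ndarray) -> Tensor:
        """Mean -log P(gold|X) over a padded batch (autodiff Tensor)."""
        bsz, length, k = emissions.shape
        gold = np.asarray(gold)
        lengths = np.asarray(lengths)
        if self.constrain:
            mt, ms, me = self._masks
            trans = self.transitions + Tensor(mt)
            start = self.start + Tensor(ms)
            stop = self.stop + Tensor(me)
        else:
            trans, start, stop = self.transitions, self.start, self.stop
        valid = np.arange(length)[None, :] < lengths[:, None]

        # gold path scores
        rows = np.arange(bsz)
        e_gold = emissions[rows[:, None], np.arange(length)[None, :], gold]
        gold_score = (e_gold * Tensor(valid.astype(np.float32))).sum(axis=1)
        t_gold = trans[gold[:, :-1], gold[:, 1:]]
        t_valid = valid[:, 1:]
        gold_score = gold_score + (t_gold * Tensor(t_valid.astype(np.float32))).sum(axis=1)
        gold_score = gold_score + start[gold[:, 0]] + stop[gold[rows, lengths - 1]]

        # forward algorithm in log space over the padded batch
        steps = [emissions[:, t, :] for t in range(length)]
        alpha = start.reshape(1, k) + steps[0]
        for t in range(1, length):
            cand = logsumexp(alpha.reshape(bsz, k, 1) + trans.reshape(1, k, k), axis=1)
            cand = cand + steps[t]
            alpha = where(valid[:, t:t + 1], cand, alpha)
        log_z = logsumexp(alpha + stop.reshape(1, k), axis=1)
        nll = log_z - gold_score
        return nll.sum() * (1.0 / bsz)

    def decode(self, emissions: np.ndarray, lengths: np.ndarray | None = None
               ) -> list[list[int]]:
        """Viterbi decode a padded batch of emission matrices (numpy, no grad)."""
        emissions = np.asarray(emissions)
        if emissions.ndim == 2:
            emissions = emissions[None]
        bsz, length, _ = emissions.shape
        if lengths is None:
            lengths = np.full(bsz, length)
        trans, start, stop = self.effective()
        return [
            viterbi_decode(emissions[b, :lengths[b]], trans, start, stop)[0]
            for b in range(bsz)
        ]
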