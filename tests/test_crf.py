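"""Linear-chain CRF against brute-force enumeration oracles."""

import itertools

import numpy as np
import pytest

from kgner.crf import (
    CRF,
    bioes_constraint_masks,
    crf_log_partition,
    crf_nll,
    crf_path_score,
    viterbi_decode,
)
from kgner.nn import Tensor
from kgner.tagging import LabelScheme, is_valid_transition


def brute_force(emissions, transitions, start, stop):
    """All path scores by explicit enumeration."""
    n, k = emissions.shape
    scores = {}
    for path in itertools.product(range(k), repeat=n):
        s = start[path[0]] + stop[path[-1]]
        s += sum(emissions[i, y] for i, y in enumerate(path))
        s += sum(transitions[a, b] for a, b in zip(path, path[1:]))
        scores[path] = s
    return scores


def random_instance(rng, n, k, scale=2.0):
    return (rng.normal(scale=scale, size=(n, k)),
            rng.normal(scale=scale, size=(k, k)),
            rng.normal(scale=scale, size=k),
            rng.normal(scale=scale, size=k))


def test_oracle_suite_200_random_instances():
    """Forward-algorithm log Z within 1e-6 relative of enumeration, and
    Viterbi equal to the enumerated argmax, over 200 random chains."""
    rng = np.random.default_rng(2024)
    for _ in range(200):
        n = int(rng.integers(1, 7))
        k = int(rng.integers(2, 6))
        em, tr, st, sp = random_instance(rng, n, k)
        scores = brute_force(em, tr, st, sp)
        vals = np.array(list(scores.values()))
        log_z = crf_log_partition(em, tr, st, sp)
        expect = np.log(np.exp(vals - vals.max()).sum()) + vals.max()
        assert abs(log_z - expect) <= 1e-6 * abs(expect)
        best_path = min(sorted(scores), key=lambda p: (-scores[p], p))
        path, best = viterbi_decode(em, tr, st, sp)
        assert tuple(path) == best_path
        assert best == pytest.approx(scores[best_path], rel=1e-9)
        # log Z dominates every single path
        assert log_z >= vals.max() - 1e-9


def test_path_score_matches_enumeration():
    rng = np.random.default_rng(5)
    em, tr, st, sp = random_instance(rng, 4, 3)
    scores = brute_force(em, tr, st, sp)
    for path, expect in scores.items():
        assert crf_path_score(em, tr, list(path), st, sp) == pytest.approx(expect)


def test_path_score_edge_cases():
    em = np.array([[1.0, 2.0]])
    tr = np.zeros((2, 2))
    st, sp = np.array([0.5, 0.0]), np.array([0.0, 0.25])
    assert crf_path_score(em, tr, [0], st, sp) == pytest.approx(1.5)
    assert crf_path_score(em, tr, [1], st, sp) == pytest.approx(2.25)
    # zero transitions: score is the sum of emissions along the path
    em2 = np.array([[1.0, 0.0], [0.0, 3.0]])
    assert crf_path_score(em2, np.zeros((2, 2)), [0, 1]) == pytest.approx(4.0)
    with pytest.raises(ValueError):
        crf_path_score(em, tr, [2], st, sp)


def test_nll_nonnegative_and_normalised():
    rng = np.random.default_rng(11)
    em, tr, st, sp = random_instance(rng, 3, 3)
    log_z = crf_log_partition(em, tr, st, sp)
    total = 0.0
    for path in itertools.product(range(3), repeat=3):
        nll = crf_nll(em, tr, list(path), st, sp)
        assert nll >= -1e-9
        total += np.exp(-nll)
    assert total == pytest.approx(1.0, abs=1e-6)  # probabilities sum to 1


def test_single_label_vocabulary_forces_nll_zero():
    em = np.zeros((4, 1))
    assert crf_nll(em, np.zeros((1, 1)), [0, 0, 0, 0]) == pytest.approx(0.0)


def test_batched_nll_matches_reference(rng):
    scheme = LabelScheme(("A",))  # 5 labels
    crf = CRF(scheme, rng)
    k = len(scheme)
    lengths = np.array([4, 2, 1])
    em = rng.normal(size=(3, 4, k)).astype(np.float32)
    gold = np.array([[0, 1, 2, 3], [4, 0, 0, 0], [2, 0, 0, 0]])
    out = crf.nll(Tensor(em), gold, lengths).item()
    tr, st, sp = crf.transitions.data, crf.start.data, crf.stop.data
    expect = np.mean([
        crf_nll(em[b, :lengths[b]].astype(np.float64), tr,
                list(gold[b, :lengths[b]]), st, sp)
        for b in range(3)
    ])
    assert out == pytest.approx(expect, rel=1e-4)


def test_batched_nll_gradient_is_finite(rng):
    scheme = LabelScheme(("A", "B"))
    crf = CRF(scheme, rng)
    em = Tensor(rng.normal(size=(2, 3, len(scheme))).astype(np.float32),
                requires_grad=True)
    loss = crf.nll(em, np.zeros((2, 3), dtype=int), np.array([3, 3]))
    loss.backward()
    assert np.isfinite(em.grad).all()
    assert np.isfinite(crf.transitions.grad).all()


def test_constrained_decoding_is_always_well_formed(rng):
    scheme = LabelScheme(("A", "B"))
    crf = CRF(scheme, rng, constrain=True)
    bad = 0
    for _ in range(300):
        n = int(rng.integers(1, 9))
        em = rng.normal(scale=3.0, size=(n, len(scheme)))
        path = crf.decode(em)[0]
        labels = [scheme.labels[j] for j in path]
        from kgner.tagging import valid_end, valid_start
        bad += not valid_start(labels[0]) or not valid_end(labels[-1])
        bad += sum(not is_valid_transition(a, b) for a, b in zip(labels, labels[1:]))
    assert bad == 0


def test_constraint_masks_agree_with_grammar():
    scheme = LabelScheme(("A",))
    trans, start, stop = bioes_constraint_masks(scheme)
    for i, a in enumerate(scheme.labels):
        for j, b in enumerate(scheme.labels):
            assert (trans[i, j] == 0.0) == is_valid_transition(a, b)


def test_viterbi_tie_break_lowest_index():
    em = np.zeros((2, 3))
    tr = np.zeros((3, 3))
    path, _ = viterbi_decode(em, tr)
    assert path == [0, 0]
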