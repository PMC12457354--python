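"""BIOES encoding/decoding, including brute-force oracle cross-checks."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kgner.tagging import (
    AnnotationError,
    DecodeError,
    LabelScheme,
    Span,
    decode_labels,
    encode_spans,
    is_valid_transition,
    read_conll,
    valid_end,
    valid_start,
    write_conll,
)

# the worked clinical example: 无 胸 闷 胸 痛 胸 前 区 压 榨 感
CLINICAL_LABELS = ["O", "S-BODY", "O", "S-BODY", "O",
                   "B-BODY", "I-BODY", "E-BODY", "O", "O", "O"]
CLINICAL_SPANS = [Span(1, 2, "BODY"), Span(3, 4, "BODY"), Span(5, 8, "BODY")]


def test_clinical_example_roundtrip():
    assert decode_labels(CLINICAL_LABELS, mode="strict") == CLINICAL_SPANS
    assert encode_spans(11, CLINICAL_SPANS) == CLINICAL_LABELS


def test_encode_edge_cases():
    assert encode_spans(5, []) == ["O"] * 5
    assert encode_spans(2, [Span(0, 2, "DRUG")]) == ["B-DRUG", "E-DRUG"]
    with pytest.raises(AnnotationError):
        encode_spans(4, [Span(0, 2, "DRUG"), Span(1, 3, "BODY")])
    with pytest.raises(AnnotationError):
        encode_spans(2, [Span(0, 3, "DRUG")])


def test_strict_decode_rejects_invalid():
    with pytest.raises(DecodeError):
        decode_labels(["I-BODY"], mode="strict")
    with pytest.raises(DecodeError):
        decode_labels(["B-BODY", "O"], mode="strict")
    with pytest.raises(DecodeError):
        decode_labels(["B-DRUG", "E-BODY"], mode="strict")
    assert decode_labels(["O", "O"], mode="strict") == []


def random_span_sets(rng, length, types, n):
    for _ in range(n):
        spans, pos = [], 0
        while pos < length:
            if rng.random() < 0.5:
                end = pos + int(rng.integers(1, min(4, length - pos) + 1))
                spans.append(Span(pos, end, types[rng.integers(len(types))]))
                pos = end + int(rng.integers(0, 2))
            else:
                pos += 1
        yield [s for s in spans if s.end <= length]


def test_roundtrip_identity_1000_random_span_sets():
    rng = np.random.default_rng(7)
    types = ("BODY", "DRUG", "TEST")
    for spans in random_span_sets(rng, 12, types, 1000):
        labels = encode_spans(12, spans)
        assert decode_labels(labels, mode="strict") == sorted(spans)
        assert decode_labels(labels, mode="lenient") == sorted(spans)


def all_span_sets(length, types):
    """Every flat span set on a sequence of the given length."""
    spans = [Span(s, e, t) for s in range(length)
             for e in range(s + 1, length + 1) for t in types]

    def rec(prefix, pos):
        yield prefix
        for sp in spans:
            if sp.start >= pos:
                yield from rec(prefix + [sp], sp.end)

    yield from rec([], 0)


def test_transition_table_matches_enumeration():
    """is_valid_transition == the set of adjacent pairs over all encodings
    of all span sets up to length 4 with 2 types."""
    types = ("A", "B")
    scheme = LabelScheme(types)
    observed = set()
    starts, ends = set(), set()
    for length in range(1, 5):
        for spans in all_span_sets(length, types):
            labels = encode_spans(length, spans)
            starts.add(labels[0])
            ends.add(labels[-1])
            observed.update(zip(labels, labels[1:]))
    for a in scheme.labels:
        for b in scheme.labels:
            assert is_valid_transition(a, b) == ((a, b) in observed), (a, b)
        assert valid_start(a) == (a in starts)
        assert valid_end(a) == (a in ends)


# -- lenient decoding vs a brute-force maximal-reading oracle ----------------

def _supported(labels, s, e):
    """Can labels[s:e] be read as one (possibly truncated) entity?"""
    typs = {lab.partition("-")[2] for lab in labels[s:e]}
    if len(typs) != 1 or "O" in [lab for lab in labels[s:e]]:
        return False
    tags = [lab.partition("-")[0] for lab in labels[s:e]]
    if e - s == 1:
        return tags[0] in "BIES"
    if tags[0] not in "BI":
        return False
    if any(t != "I" for t in tags[1:-1]):
        return False
    return tags[-1] in "IE"


def oracle_lenient(labels):
    """Enumerate all non-overlapping sets of supported spans; return the one
    maximising coverage, then minimising span count, then leftmost-longest."""
    n = len(labels)
    candidates = [(s, e) for s in range(n) for e in range(s + 1, n + 1)
                  if _supported(labels, s, e)]
    best = None

    def rec(chosen, pos):
        nonlocal best
        key = (sum(e - s for s, e in chosen), -len(chosen),
               tuple((-s, e) for s, e in chosen))
        if best is None or key > best[0]:
            best = (key, list(chosen))
        for c in candidates:
            if c[0] >= pos:
                rec(chosen + [c], c[1])

    rec([], 0)
    return [Span(s, e, labels[s].partition("-")[2]) for s, e in best[1]]


label_strategy = st.lists(
    st.sampled_from(["O"] + [f"{t}-{y}" for t in "BIES" for y in ("X", "Y")]),
    min_size=1, max_size=7,
)


@settings(max_examples=300, deadline=None, derandomize=True)
@given(label_strategy)
def test_lenient_decoding_matches_maximal_reading_oracle(labels):
    assert decode_labels(labels, mode="lenient") == sorted(oracle_lenient(labels))


def test_lenient_truncation_example():
    # open DRUG run truncates at its last consistent position; the
    # type-switched remainder still closes as its own entity
    got = decode_labels(["B-DRUG", "I-BODY", "E-BODY"], mode="lenient")
    assert got == [Span(0, 1, "DRUG"), Span(1, 3, "BODY")]
    assert decode_labels(["O", "O", "O"], mode="lenient") == []


def test_label_scheme_vocabulary():
    scheme = LabelScheme(("A", "B", "C"))
    assert len(scheme) == 13 and scheme.labels[0] == "O"
    assert scheme.index("B-A") == 1
    with pytest.raises(KeyError):
        scheme.index("B-Z")


def test_conll_roundtrip(tmp_path):
    sentences = [("胸前区", ["B-BODY", "I-BODY", "E-BODY"]), ("无", ["O"])]
    path = tmp_path / "c.conll"
    write_conll(path, sentences)
    assert read_conll(path) == sentences
    with pytest.raises(ValueError, match=":1"):
        bad = tmp_path / "bad.conll"
        bad.write_text("too many\tcolumns\there\n", encoding="utf-8")
        read_conll(bad)
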