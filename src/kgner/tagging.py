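"""BIOES span labelling for character-level NER.

Entities are flat, non-overlapping, typed character spans.  Coordinates are
0-based and half-open throughout the package: a span ``(start, end, type)``
covers characters ``start .. end-1``.  The tag grammar is

* ``S-T`` — a single-character entity of type ``T``
* ``B-T  I-T* E-T`` — a multi-character entity (Begin, Inside..., End)
* ``O`` — outside any entity

which is strictly finer than BIO and lets the decoder recover exact
boundaries without lookahead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

DEFAULT_ENTITY_TYPES = ("BODY", "DRUG", "DISEASES", "EXAMINATIONS", "TEST", "TREATMENT")
# The six-type clinical benchmark schema (disease/diagnosis, surgery, drug,
# anatomy, imaging exam, laboratory exam) selectable as an alternative.
CCKS_ENTITY_TYPES = ("Dis", "Operation", "Drug", "Anatomy", "ImgExam", "LabExam")


class AnnotationError(ValueError):
    """Raised for overlapping spans or malformed gold label sequences."""


@dataclass(frozen=True, order=True)
class Span:
    start: int
    end: int  # exclusive
    entity_type: str

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise AnnotationError(f"invalid span bounds ({self.start}, {self.end})")
        if not self.entity_type:
            raise AnnotationError("empty entity type")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class LabelScheme:
    """Ordered BIOES label vocabulary over a closed set of entity types."""

    entity_types: tuple[str, ...] = DEFAULT_ENTITY_TYPES
    labels: tuple[str, ...] = field(init=False)

    def __post_init__(self):
        self.entity_types = tuple(self.entity_types)
        labs = ["O"]
        for t in self.entity_types:
            labs += [f"B-{t}", f"I-{t}", f"E-{t}", f"S-{t}"]
        self.labels = tuple(labs)
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(f"label {label!r} not in scheme") from None

    def split(self, label: str) -> tuple[str, str | None]:
        """Return (tag, entity_type); type is None for O."""
        if label == "O":
            return "O", None
        tag, _, typ = label.partition("-")
        return tag, typ

    def type_index(self, entity_type: str) -> int:
        return self.entity_types.index(entity_type)


def encode_spans(length: int, spans: list[Span] | set[Span],
                 scheme: LabelScheme | None = None) -> list[str]:
    """Encode non-overlapping spans over a length-``length`` sequence as BIOES."""
    spans = sorted(spans)
    for s in spans:
        if s.end > length:
            raise AnnotationError(f"span {s} exceeds sequence length {length}")
        if scheme is not None and s.entity_type not in scheme.entity_types:
            raise AnnotationError(f"unknown entity type {s.entity_type!r}")
    for a, b in zip(spans, spans[1:]):
        if a.end > b.start:
            raise AnnotationError(f"overlapping spans {a} and {b}")
    labels = ["O"] * length
    for s in spans:
        if s.length == 1:
            labels[s.start] = f"S-{s.entity_type}"
        else:
            labels[s.start] = f"B-{s.entity_type}"
            for i in range(s.start + 1, s.end - 1):
                labels[i] = f"I-{s.entity_type}"
            labels[s.end - 1] = f"E-{s.entity_type}"
    return labels


class DecodeError(ValueError):
    """Raised by strict decoding on a label sequence no encoding produces."""


def _parse(label: str) -> tuple[str, str | None]:
    if label == "O":
        return "O", None
    tag, sep, typ = label.partition("-")
    if tag not in "BIES" or not sep or not typ:
        raise DecodeError(f"malformed label {label!r}")
    return tag, typ


def decode_labels(labels: list[str], mode: str = "strict") -> list[Span]:
    """Decode a BIOES label sequence back to spans.

    strict  — exact inverse of :func:`encode_spans`; any sequence that no
              valid encoding produces raises :class:`DecodeError` naming the
              first offending position.
    lenient — for raw model output: S always yields a span; a B/I run of one
              type closed by a matching E yields a full span; a dangling run
              (hitting O, a type switch, a fresh B/S, or end of sequence)
              is truncated at its last type-consistent position; a stray E
              yields a single-character span.  Every non-O position ends up
              covered by exactly one span.
    """
    if mode not in ("strict", "lenient"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "strict":
        return _decode_strict(labels)
    return _decode_lenient(labels)


def _decode_strict(labels: list[str]) -> list[Span]:
    spans: list[Span] = []
    i, n = 0, len(labels)
    while i < n:
        tag, typ = _parse(labels[i])
        if tag == "O":
            i += 1
        elif tag == "S":
            spans.append(Span(i, i + 1, typ))
            i += 1
        elif tag == "B":
            j = i + 1
            while j < n and labels[j] == f"I-{typ}":
                j += 1
            if j >= n or labels[j] != f"E-{typ}":
                raise DecodeError(
                    f"position {i}: B-{typ} run not closed by E-{typ} "
                    f"(broken at position {min(j, n - 1)})"
                )
            spans.append(Span(i, j + 1, typ))
            i = j + 1
        else:  # I or E without a preceding B
            raise DecodeError(f"position {i}: stray {labels[i]} without B-{typ}")
    return spans


def _decode_lenient(labels: list[str]) -> list[Span]:
    spans: list[Span] = []
    i, n = 0, len(labels)
    while i < n:
        tag, typ = _parse(labels[i])
        if tag == "O":
            i += 1
        elif tag in ("S", "E"):
            spans.append(Span(i, i + 1, typ))
            i += 1
        else:  # B or I opens a run of this type
            j = i + 1
            while j < n and labels[j] == f"I-{typ}":
                j += 1
            if j < n and labels[j] == f"E-{typ}":
                spans.append(Span(i, j + 1, typ))
                i = j + 1
            else:  # truncate at the last type-consistent position
                spans.append(Span(i, j, typ))
                i = j
    return spans


def is_valid_transition(prev: str, nxt: str) -> bool:
    """True iff ``prev -> nxt`` can occur inside some encode_spans output."""
    ptag, ptyp = _parse(prev)
    ntag, ntyp = _parse(nxt)
    if ptag in ("O", "E", "S"):
        return ntag in ("O", "B", "S")
    # inside an open entity: only continue or close it, same type
    return ntag in ("I", "E") and ntyp == ptyp


def valid_start(label: str) -> bool:
    tag, _ = _parse(label)
    return tag in ("O", "B", "S")


def valid_end(label: str) -> bool:
    tag, _ = _parse(label)
    return tag in ("O", "E", "S")


# -- CoNLL-style corpus I/O --------------------------------------------------

def read_conll(path) -> list[tuple[str, list[str]]]:
    """Read a character-per-line corpus: ``char<TAB>label``, blank line
    between sentences.  Returns ``[(text, labels), ...]``."""
    sentences: list[tuple[str, list[str]]] = []
    chars: list[str] = []
    labels: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                if chars:
                    sentences.append(("".join(chars), labels))
                    chars, labels = [], []
                continue
            parts = line.split("\t")
            if len(parts) != 2 or len(parts[0]) != 1:
                raise ValueError(f"{path}:{lineno}: expected 'char<TAB>label', got {line!r}")
            chars.append(parts[0])
            labels.append(parts[1])
    if chars:
        sentences.append(("".join(chars), labels))
    return sentences


def write_conll(path, sentences: list[tuple[str, list[str]]]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for text, labels in sentences:
            if len(text) != len(labels):
                raise ValueError("text/label length mismatch")
            for ch, lab in zip(text, labels):
                fh.write(f"{ch}\t{lab}\n")
            fh.write("\n")
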