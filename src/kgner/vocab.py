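"""Character vocabulary with the special tokens the encoder expects."""

from __future__ import annotations

PAD, CLS, SEP, MASK, UNK = "[PAD]", "[CLS]", "[SEP]", "[MASK]", "[UNK]"
SPECIALS = (PAD, CLS, SEP, MASK, UNK)


class Vocabulary:
    def __init__(self, tokens: list[str]):
        for i, sp in enumerate(SPECIALS):
            if tokens[i] != sp:
                raise ValueError(f"token {i} must be {sp}, got {tokens[i]!r}")
        self.tokens = list(tokens)
        self.index = {t: i for i, t in enumerate(tokens)}
        if len(self.index) != len(tokens):
            raise ValueError("duplicate tokens in vocabulary")

    def __len__(self) -> int:
        return len(self.tokens)

    @classmethod
    def from_texts(cls, texts) -> "Vocabulary":
        chars = sorted({ch for text in texts for ch in text})
        return cls(list(SPECIALS) + chars)

    def encode(self, text: str) -> list[int]:
        unk = self.index[UNK]
        return [self.index.get(ch, unk) for ch in text]

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\n".join(self.tokens) + "\n")

    @classmethod
    def load(cls, path) -> "Vocabulary":
        with open(path, encoding="utf-8") as fh:
            return cls([line.rstrip("\n") for line in fh if line.rstrip("\n")])

    @property
    def pad_id(self) -> int:
        return self.index[PAD]

    @property
    def cls_id(self) -> int:
        return self.index[CLS]

    @property
    def sep_id(self) -> int:
        return self.index[SEP]
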