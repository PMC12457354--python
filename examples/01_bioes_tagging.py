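"""BIOES span labelling: encode typed spans to tags and decode them back.

The sequence below is the clinical phrase 无胸闷胸痛胸前区压榨感
("no chest tightness, chest pain, precordial crushing sensation") with
three anatomical-part (BODY) mentions.
"""

from kgner.tagging import Span, decode_labels, encode_spans

text = "无胸闷胸痛胸前区压榨感"
spans = [Span(1, 2, "BODY"), Span(3, 4, "BODY"), Span(5, 8, "BODY")]

labels = encode_spans(len(text), spans)
for ch, lab in zip(text, labels):
    print(f"{ch}\t{lab}")

recovered = decode_labels(labels, mode="strict")
print("\ndecoded spans:", [(s.start, s.end, s.entity_type) for s in recovered])
print("round-trip exact:", recovered == spans)
# Single characters get S-, multi-character mentions get B- .. E-; strict
# decoding inverts the encoding exactly, so the final line must print True.
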