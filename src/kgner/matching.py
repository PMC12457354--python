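"""Forward maximum matching of lexicon surface forms over character text.

This single matcher backs both the lexicon-derived character features and the
entity-linking step of knowledge fusion, so the two are consistent by
construction: a character carries a non-O position feature exactly when it is
linked to a KG entity.
"""

from __future__ import annotations

from dataclasses import dataclass

from .kg import SurfaceLexicon


@dataclass(frozen=True)
class Match:
    start: int
    end: int  # exclusive
    entity_id: int
    entity_type: str
    surface: str


def forward_max_match(text: str, lex: SurfaceLexicon) -> list[Match]:
    """Scan left to right; at each position take the longest lexicon surface
    starting there (ties impossible: lengths differ), consume it, continue.
    Unmatched characters are skipped one at a time."""
    matches: list[Match] = []
    i, n = 0, len(text)
    if lex.max_len == 0:
        return matches
    while i < n:
        hit = None
        for length in range(min(lex.max_len, n - i), 0, -1):
            cand = text[i:i + length]
            entry = lex.lookup(cand)
            if entry is not None:
                hit = Match(i, i + length, entry[0], entry[1], cand)
                break
        if hit is None:
            i += 1
        else:
            matches.append(hit)
            i = hit.end
    return matches
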