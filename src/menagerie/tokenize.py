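"""Shared tokenization for annotation, feature extraction and matching.

Hyphen and slash are token boundaries, so surface variants such as
``MPTP/probenecid`` or ``6-hydroxydopamine`` decompose into comparable word
tokens.  An apostrophe between alphanumerics stays inside the token
(``Parkinson's``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

# Word: alphanumeric runs, optionally joined by an internal apostrophe.
_WORD_RE = re.compile(r"[A-Za-z0-9]+(?:['’][A-Za-z0-9]+)*")
# Punctuation tokens that close scopes / delimit phrases.
_PUNCT_RE = re.compile(r"[.,;:!?()\[\]]")

_TOKEN_RE = re.compile(f"({_WORD_RE.pattern})|({_PUNCT_RE.pattern})")


@dataclass(frozen=True)
class Token:
    text: str
    start: int
    end: int
    is_word: bool

    def folded(self) -> str:
        return self.text.casefold().replace("’", "'")


def tokenize(text: str) -> list[Token]:
    """Split *text* into word and punctuation tokens with character offsets."""
    out = []
    for m in _TOKEN_RE.finditer(text):
        out.append(Token(m.group(0), m.start(), m.end(), m.group(1) is not None))
    return out


def word_tokens(text: str) -> list[Token]:
    return [t for t in tokenize(text) if t.is_word]


def fold_tokens(text: str) -> tuple[str, ...]:
    """Case-folded word-token tuple; the canonical key for dictionary entries."""
    return tuple(t.folded() for t in tokenize(text) if t.is_word)
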