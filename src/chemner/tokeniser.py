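"""Chemistry-aware tokenisation.

Chemical names are fragile under ordinary tokenisation: hyphens, internal
brackets, locant commas, charge signs and Greek letters are all meaningful
inside a name ("Metallo-β-lactamase", "C2(MONO)", "1,2-diol", "Cu2+").  The
default tokeniser splits on whitespace and then iteratively detaches
sentence punctuation from token edges, with three exceptions that keep
chemical names intact:

* **balanced-bracket rule** — an edge bracket is retained when its mate lies
  inside the same whitespace-delimited chunk ("C2(MONO)", "(ii)");
* **locant rule** — a comma flanked by digits is never an edge character, so
  "1,2-diol" survives untouched;
* **charge rule** — terminal ``+``/``−`` are not sentence punctuation and are
  always retained ("Cu2+").

Internal hyphens (ASCII hyphen-minus, minus sign U+2212, hyphen U+2010) are
never split.  ``naive_tokenise`` is the deliberately crude whitespace-only
baseline used in tokenisation-ablation experiments.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, asdict

from .annotations import SourceDocument, Token

__all__ = ["TokeniserConfig", "tokenise", "naive_tokenise"]

_WS_TOKEN = re.compile(r"\S+")

#: punctuation detached from token edges (hyphens and +/− deliberately absent)
_SENT_PUNCT = frozenset('.,;:!?"\'()[]')
_OPEN = {"(": ")", "[": "]"}
_CLOSE = {")": "(", "]": "["}


@dataclass(frozen=True)
class TokeniserConfig:
    """Flags controlling the refinement pipeline; all default on.

    Serialisable (``to_dict``/``from_dict``) so workflow variants are
    reproducible from configuration alone.
    """

    preserve_internal_hyphens: bool = True
    preserve_balanced_brackets: bool = True
    split_sentence_punct: bool = True
    unicode_nfc: bool = True

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TokeniserConfig":
        return cls(**d)


def _has_closing_mate(text: str, i: int, end: int) -> bool:
    """True if the opening bracket at ``i`` is closed within [i, end)."""
    opener = text[i]
    closer = _OPEN[opener]
    depth = 0
    for j in range(i, end):
        if text[j] == opener:
            depth += 1
        elif text[j] == closer:
            depth -= 1
            if depth == 0:
                return True
    return False


def _has_opening_mate(text: str, start: int, i: int) -> bool:
    """True if the closing bracket at ``i`` is opened within [start, i]."""
    closer = text[i]
    opener = _CLOSE[closer]
    depth = 0
    for j in range(i, start - 1, -1):
        if text[j] == closer:
            depth += 1
        elif text[j] == opener:
            depth -= 1
            if depth == 0:
                return True
    return False


def _refine(text: str, start: int, end: int, cfg: TokeniserConfig
            ) -> list[tuple[int, int]]:
    """Split one whitespace-delimited chunk into refined token spans."""
    leading: list[tuple[int, int]] = []
    trailing: list[tuple[int, int]] = []
    cs, ce = start, end
    while ce - cs > 1:
        ch = text[cs]
        if ch in _SENT_PUNCT:
            keep = (cfg.preserve_balanced_brackets and ch in _OPEN
                    and _has_closing_mate(text, cs, ce))
            if not keep:
                leading.append((cs, cs + 1))
                cs += 1
                continue
        ch = text[ce - 1]
        if ch in _SENT_PUNCT:
            keep = (cfg.preserve_balanced_brackets and ch in _CLOSE
                    and _has_opening_mate(text, cs, ce - 1))
            if not keep:
                trailing.append((ce - 1, ce))
                ce -= 1
                continue
        break
    return leading + [(cs, ce)] + trailing[::-1]


def tokenise(document: SourceDocument | str,
             config: TokeniserConfig | None = None) -> list[Token]:
    """Tokenise a document with the chemistry-aware rule pipeline.

    Deterministic and total: any string yields an ordered, non-overlapping,
    offset-faithful token list.  With ``unicode_nfc`` set the text is viewed
    in NFC form (the identity for documents produced by this package's
    readers, which normalise at construction).
    """
    cfg = config or TokeniserConfig()
    text = document.text if isinstance(document, SourceDocument) else document
    if cfg.unicode_nfc:
        text = unicodedata.normalize("NFC", text)
    tokens: list[Token] = []
    for m in _WS_TOKEN.finditer(text):
        if cfg.split_sentence_punct:
            spans = _refine(text, m.start(), m.end(), cfg)
        else:
            spans = [(m.start(), m.end())]
        for s, e in spans:
            tokens.append(Token(surface=text[s:e], start=s, end=e))
    return tokens


def naive_tokenise(document: SourceDocument | str) -> list[Token]:
    """Whitespace-only splitting: punctuation stays glued to words.

    The baseline for tokenisation-ablation experiments — it pollutes chemical
    names adjacent to punctuation ("bis-monodentate." stays one token), which
    misaligns gold entity boundaries downstream.
    """
    text = document.text if isinstance(document, SourceDocument) else document
    return [Token(surface=m.group(), start=m.start(), end=m.end())
            for m in _WS_TOKEN.finditer(text)]
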