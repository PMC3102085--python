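"""Deterministic pattern recogniser: dictionary, finite-state rules, n-gram scorer.

Three knowledge sources produce candidate spans:

1. **dictionary** — longest-match lookup of token windows (up to 5 tokens)
   against a chemical lexicon;
2. **rules** — named finite-state patterns over token surfaces (locant
   prefixes, charged formulas, Greek-hyphenated stems, metal oxidation
   states);
3. **scorer** — a two-class character n-gram model classifying single tokens
   by length-normalised log-likelihood ratio (chemical vs non-chemical).

Overlaps resolve longest-match-first, ties leftmost, then by source priority
dictionary > rule > scorer.  The recogniser contains no randomness and no
fitted classification model: identical inputs always give identical outputs.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

from .annotations import EntitySpan, Token

__all__ = [
    "ChemicalLexicon",
    "NGramScorer",
    "PatternRule",
    "PatternRuleSet",
    "build_scorer",
    "score_word",
    "recognise",
    "default_rules",
]

_UNK = "\x00"  # unknown-character class
_END = "$"
_PAD = "^"

_METALS = ("ruthenium|copper|iron|zinc|platinum|palladium|cobalt|nickel|"
           "osmium|gold|silver|manganese|rhodium|iridium")


@dataclass(frozen=True)
class ChemicalLexicon:
    """Chemical word list plus known non-chemical stop words (disjoint sets).

    Lookup is case-sensitive with a case-insensitive fallback for
    initial-capital forms (sentence-position capitalisation).  Multiword
    entries are whitespace-normalized.
    """

    chemical_words: frozenset[str]
    stop_words: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        overlap = self.chemical_words & self.stop_words
        if overlap:
            raise ValueError(f"lexicon and stop list overlap: {sorted(overlap)[:5]}")

    @classmethod
    def from_words(cls, chemical, stop=()) -> "ChemicalLexicon":
        norm = lambda w: " ".join(w.split())
        return cls(chemical_words=frozenset(map(norm, chemical)),
                   stop_words=frozenset(map(norm, stop)))

    def contains(self, phrase: str) -> bool:
        if phrase in self.chemical_words:
            return True
        if phrase[:1].isupper():
            return (phrase[0].lower() + phrase[1:]) in self.chemical_words
        return False

    def is_stop(self, word: str) -> bool:
        return word in self.stop_words or word.lower() in self.stop_words


@dataclass(frozen=True)
class NGramScorer:
    """Two add-α-smoothed character n-gram models (chemical / non-chemical).

    Contexts are the ``order-1`` preceding characters with ``^`` padding;
    every conditional distribution ranges over the training alphabet plus an
    end-of-word symbol and an unknown-character class, and sums to one by
    construction.
    """

    order: int
    alphabet: frozenset[str]
    chem_counts: dict[str, dict[str, int]]
    nonchem_counts: dict[str, dict[str, int]]
    chem_totals: dict[str, int]
    nonchem_totals: dict[str, int]
    alpha: float = 0.01

    @property
    def n_outcomes(self) -> int:
        return len(self.alphabet) + 2  # + end symbol + unknown class

    def _norm_char(self, ch: str) -> str:
        return ch if ch in self.alphabet or ch == _END else _UNK

    def log_prob(self, word: str, model: str) -> float:
        counts = self.chem_counts if model == "chem" else self.nonchem_counts
        totals = self.chem_totals if model == "chem" else self.nonchem_totals
        padded = _PAD * (self.order - 1) + word + _END
        lp = 0.0
        V = self.n_outcomes
        for j in range(self.order - 1, len(padded)):
            ctx = "".join(self._norm_char(c) if c != _PAD else _PAD
                          for c in padded[j - self.order + 1:j])
            ch = self._norm_char(padded[j])
            c = counts.get(ctx, {}).get(ch, 0)
            t = totals.get(ctx, 0)
            lp += math.log((c + self.alpha) / (t + self.alpha * V))
        return lp


def build_scorer(chemical_words, nonchemical_words, order: int = 4,
                 smoothing: float = 0.01) -> NGramScorer:
    """Estimate both character models by maximum likelihood with add-α smoothing."""
    chemical_words = list(chemical_words)
    nonchemical_words = list(nonchemical_words)
    if not chemical_words or not nonchemical_words:
        raise ValueError("both training word lists must be non-empty")
    alphabet = frozenset("".join(chemical_words) + "".join(nonchemical_words))

    def count(words):
        counts: dict[str, dict[str, int]] = {}
        totals: dict[str, int] = {}
        for w in words:
            padded = _PAD * (order - 1) + w + _END
            for j in range(order - 1, len(padded)):
                ctx = padded[j - order + 1:j]
                ch = padded[j]
                counts.setdefault(ctx, {})
                counts[ctx][ch] = counts[ctx].get(ch, 0) + 1
                totals[ctx] = totals.get(ctx, 0) + 1
        return counts, totals

    cc, ct = count(chemical_words)
    nc, nt = count(nonchemical_words)
    return NGramScorer(order=order, alphabet=alphabet, chem_counts=cc,
                       nonchem_counts=nc, chem_totals=ct, nonchem_totals=nt,
                       alpha=smoothing)


def score_word(scorer: NGramScorer, word: str) -> float:
    """Length-normalised log-likelihood ratio; positive ⇒ chemical.

    Normalised by the number of emission events (``len(word) + 1`` including
    the end symbol), so scores are comparable across word lengths.  Exactly
    antisymmetric under swapping the two training lists.
    """
    if not word:
        raise ValueError("cannot score an empty word")
    lr = scorer.log_prob(word, "chem") - scorer.log_prob(word, "nonchem")
    return lr / (len(word) + 1)


@dataclass(frozen=True)
class PatternRule:
    """A named finite-state pattern; each regex must match one whole token."""

    name: str
    token_patterns: tuple[re.Pattern, ...]

    @classmethod
    def compile(cls, name: str, *patterns: str) -> "PatternRule":
        return cls(name=name, token_patterns=tuple(
            re.compile(p) for p in patterns))

    def match_at(self, surfaces: list[str], i: int) -> bool:
        if i + len(self.token_patterns) > len(surfaces):
            return False
        return all(p.fullmatch(surfaces[i + k])
                   for k, p in enumerate(self.token_patterns))


@dataclass(frozen=True)
class PatternRuleSet:
    rules: tuple[PatternRule, ...]

    def __post_init__(self) -> None:
        names = [r.name for r in self.rules]
        if len(set(names)) != len(names):
            raise ValueError("rule names must be unique")


def default_rules() -> PatternRuleSet:
    """Name-morphology rules covering common systematic-name shapes."""
    return PatternRuleSet(rules=(
        # 2,4-dichlorohexan-1-ol and friends
        PatternRule.compile("locant_substituent",
                            r"\d+(?:,\d+)*-[A-Za-zͰ-Ͽ][\w,-]*"),
        # Cu2+, Zn2+, Fe3+ — element symbols, digits, charge suffix
        PatternRule.compile("formula_charge",
                            r"(?:[A-Z][a-z]?\d*)+[+−-]?[+−]"),
        # β-lactam style
        PatternRule.compile("greek_hyphenated", r"[Ͱ-Ͽ]-[A-Za-z][\w-]*"),
        # ruthenium (ii)
        PatternRule.compile("metal_oxidation",
                            _METALS, r"\((?:i{1,3}|iv|v|vi{0,3}|ix|x)\)"),
        # ruthenium (ii) diimine
        PatternRule.compile("metal_complex",
                            _METALS, r"\((?:i{1,3}|iv|v|vi{0,3}|ix|x)\)",
                            r"[a-z]{3,}"),
    ))


_PRIORITY = {"dictionary": 0, "rule": 1, "scorer": 2}
_MAX_WINDOW = 5


def _window_phrase(tokens: list[Token], i: int, j: int) -> str:
    """Whitespace-normalised surface of tokens[i..j] (inclusive)."""
    return " ".join(t.surface for t in tokens[i:j + 1])


def recognise(tokens: list[Token], lexicon: ChemicalLexicon,
              scorer: NGramScorer | None = None,
              rules: PatternRuleSet | None = None,
              text: str | None = None) -> list[EntitySpan]:
    """Run all three knowledge sources and resolve overlaps deterministically.

    Stop words suppress *scorer* candidates only; dictionary and rule matches
    always stand.  Returned spans are sorted, non-overlapping, carry the
    firing source in ``provenance``, and have no confidence (the recogniser
    is deterministic).
    """
    surfaces = [t.surface for t in tokens]
    candidates: list[tuple[int, int, str]] = []  # (first_tok, last_tok, source)

    for i in range(len(tokens)):
        for j in range(min(i + _MAX_WINDOW, len(tokens)) - 1, i - 1, -1):
            if lexicon.contains(_window_phrase(tokens, i, j)):
                candidates.append((i, j, "dictionary"))

    if rules is not None:
        for rule in rules.rules:
            width = len(rule.token_patterns)
            for i in range(len(tokens) - width + 1):
                if rule.match_at(surfaces, i):
                    candidates.append((i, i + width - 1, f"rule:{rule.name}"))

    if scorer is not None:
        for i, t in enumerate(tokens):
            if not any(ch.isalpha() for ch in t.surface):
                continue
            if lexicon.is_stop(t.surface):
                continue
            if score_word(scorer, t.surface) > 0:
                candidates.append((i, i, "scorer"))

    def rank(cand):
        i, j, source = cand
        length = tokens[j].end - tokens[i].start
        prio = _PRIORITY.get(source.split(":")[0], 9)
        return (-length, tokens[i].start, prio)

    chosen: list[tuple[int, int, str]] = []
    occupied: list[tuple[int, int]] = []
    for i, j, source in sorted(candidates, key=rank):
        s, e = tokens[i].start, tokens[j].end
        if any(s < oe and os_ < e for os_, oe in occupied):
            continue
        occupied.append((s, e))
        chosen.append((i, j, source))

    entities = []
    for i, j, source in sorted(chosen, key=lambda c: c[0]):
        s, e = tokens[i].start, tokens[j].end
        surface = text[s:e] if text is not None else _window_phrase(tokens, i, j)
        entities.append(EntitySpan(start=s, end=e, surface=surface,
                                   label="CM", provenance=source))
    return entities
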