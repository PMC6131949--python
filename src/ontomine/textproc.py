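"""Linguistic preprocessing: sentence segmentation, tokenization, POS
tagging, Porter stemming and stop-word flagging.

The pipeline only consumes a coarse part-of-speech signal downstream (verb
tokens are excluded from concept candidates), so tagging is rule-based: a
pinned verb lexicon plus conservative suffix heuristics, with nouns as the
default class. Stop words are *flagged*, never deleted, so token indices
remain valid for span arithmetic and pattern matching.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field, replace
from importlib import resources

from . import porter

__all__ = [
    "Token",
    "Sentence",
    "segment",
    "analyze",
    "normalize_text",
    "content_stems",
    "stopwords",
]

_TOKEN_RE = re.compile(r"\w+(?:'\w+)?|[^\w\s]", re.UNICODE)
_SENT_RE = re.compile(r"[^.!?]*[.!?]+(?:\s+|$)|[^.!?]+$", re.DOTALL)
_WS_RE = re.compile(r"\s+")

# Closed verb lexicon covering the verbs that occur in the shipped corpus
# generators plus common biomedical reporting verbs. Unknown words default
# to noun, which is the safe direction for dictionary-based concept lookup.
_VERBS = frozenset(
    """
    cause causes caused causing treat treats treated treating affect affects
    affected involve involves involved include includes included show shows
    shown find finds found induce induces induced associate associates
    increase increases decrease decreases report reports reported suggest
    suggests indicate indicates occur occurs develop develops result results
    require requires contain contains present presents exhibit exhibits
    reveal reveals remain remains appear appears produce produces inhibit
    inhibits activate activates regulate regulates bind binds mediate
    mediates express expresses expressed link links linked observe observes
    observed jump jumps jumped study studied examine examines examined
    describe describes described accompany accompanies accompanied
    """.split()
)


def _load_stopwords() -> frozenset[str]:
    text = (
        resources.files("ontomine")
        .joinpath("data/stopwords.txt")
        .read_text(encoding="utf-8")
    )
    words = set()
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            words.add(line.lower())
    return frozenset(words)


stopwords: frozenset[str] = _load_stopwords()


def normalize_text(text: str) -> str:
    """NFC-normalize, case-fold and collapse internal whitespace."""
    text = unicodedata.normalize("NFC", text)
    return _WS_RE.sub(" ", text).strip().casefold()


def content_stems(text: str) -> set[str]:
    """Set of Porter stems of the non-stop-word tokens of ``text``.

    The unit used for gloss-overlap disambiguation and definition
    relatedness: one entry per stem type, punctuation dropped.
    """
    out = set()
    for m in _TOKEN_RE.finditer(unicodedata.normalize("NFC", text)):
        tok = m.group(0)
        if not any(c.isalnum() for c in tok):
            continue
        if tok.lower() in stopwords:
            continue
        out.add(porter.stem(tok))
    return out


@dataclass(frozen=True)
class Token:
    surface: str
    stem: str
    pos: str
    index: int
    is_stop: bool
    char_start: int
    char_end: int


@dataclass(frozen=True)
class Sentence:
    text: str
    tokens: tuple[Token, ...] = ()
    doc_id: str = ""
    sentence_index: int = 0


def segment(text: str, doc_id: str = "") -> list[Sentence]:
    """Split ``text`` into sentences at ``.!?`` boundaries.

    Empty input yields an empty list. Sentence texts are stripped of
    surrounding whitespace; interior whitespace is preserved.
    """
    sentences: list[Sentence] = []
    for m in _SENT_RE.finditer(text):
        chunk = m.group(0).strip()
        if chunk:
            sentences.append(
                Sentence(text=chunk, doc_id=doc_id, sentence_index=len(sentences))
            )
    return sentences


def _tag(surface: str) -> str:
    lower = surface.lower()
    if not any(c.isalnum() for c in surface):
        return "."
    if lower in stopwords:
        return "DT"
    if lower.isdigit():
        return "CD"
    if lower in _VERBS:
        return "VB"
    if len(lower) >= 5 and lower.endswith("ing") and lower.isalpha():
        return "VB"
    if len(lower) >= 4 and lower.endswith("ed") and lower.isalpha():
        return "VB"
    return "NN"


def analyze(sentence: Sentence) -> Sentence:
    """Populate tokens with surface, Porter stem, POS tag and stop flag.

    Pure and idempotent: re-analysing the returned sentence reproduces it.
    """
    tokens: list[Token] = []
    for m in _TOKEN_RE.finditer(sentence.text):
        surface = m.group(0)
        tokens.append(
            Token(
                surface=surface,
                stem=porter.stem(surface) or surface.lower(),
                pos=_tag(surface),
                index=len(tokens),
                is_stop=surface.lower() in stopwords,
                char_start=m.start(),
                char_end=m.end(),
            )
        )
    return replace(sentence, tokens=tuple(tokens))
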