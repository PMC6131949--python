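"""Lexico-syntactic pattern matching for non-taxonomic relations.

Patterns are templates with one ``[X]`` and one ``[Y]`` slot around literal
word sequences, each mapped to a target-vocabulary predicate. A pattern
matches a sentence when its literal tokens occur (case-insensitively, with
a Porter-stem fallback for inflection) and the slot gaps next to them fill
with discovered concepts — by surface form first, then by any known
synonym. The default repository shipped with the package holds six curated
template→predicate mappings.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from rdflib import URIRef

from . import porter
from .enrichment import EnrichedConcept
from .textproc import Sentence, analyze, normalize_text
from .triples import RelatednessScore, TripleCandidate

__all__ = ["Pattern", "PatternRepository", "load_patterns", "default_patterns", "match_sentence"]

_SLOT_RE = re.compile(r"\[([XY])\]")
_ZERO = RelatednessScore(0.0, 0.0, 0.0, 0.0)

_MAX_SLOT_TOKENS = 8


@dataclass(frozen=True)
class Pattern:
    template: str
    observed_relation: str
    predicate: URIRef

    def __post_init__(self):
        slots = _SLOT_RE.findall(self.template)
        if sorted(slots) != ["X", "Y"]:
            raise ValueError(
                f"template {self.template!r} must contain exactly one [X] "
                "and one [Y]"
            )
        if not str(self.predicate).strip():
            raise ValueError("pattern predicate must be a non-empty IRI")
        between = _SLOT_RE.split(self.template)[2]
        if not between.strip():
            raise ValueError(
                f"template {self.template!r} needs literal words between "
                "the slots"
            )

    def parts(self) -> tuple[list[str], list[str], list[str], bool]:
        """(literal before first slot, between slots, after second slot,
        x_first) with literals lower-cased and tokenized on whitespace."""
        pieces = _SLOT_RE.split(self.template)
        # pieces = [lit, slot, lit, slot, lit]
        lit0, slot1, lit1, slot2, lit2 = pieces
        return (
            lit0.lower().split(),
            lit1.lower().split(),
            lit2.lower().split(),
            slot1 == "X",
        )


class PatternRepository:
    """Validated, de-duplicated collection of patterns."""

    def __init__(self, patterns: list[Pattern] | None = None):
        seen: set[tuple[str, URIRef]] = set()
        self.patterns: list[Pattern] = []
        for pat in patterns or ():
            key = (pat.template, pat.predicate)
            if key not in seen:
                seen.add(key)
                self.patterns.append(pat)

    def __iter__(self):
        return iter(self.patterns)

    def __len__(self) -> int:
        return len(self.patterns)


def _parse_rows(rows, origin: str) -> PatternRepository:
    patterns = []
    for lineno, row in rows:
        try:
            patterns.append(
                Pattern(
                    template=row["template"].strip(),
                    observed_relation=(row.get("observed_relation") or "").strip(),
                    predicate=URIRef(row["predicate"].strip()),
                )
            )
        except (KeyError, ValueError) as exc:
            raise ValueError(f"{origin}, row {lineno}: {exc}") from exc
    return PatternRepository(patterns)


def load_patterns(path: str | Path) -> PatternRepository:
    """Load a pattern repository from TSV (with header) or a JSON array of
    objects with fields template, observed_relation, predicate."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text(encoding="utf-8"))
        return _parse_rows(enumerate(data, start=1), str(path))
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        return _parse_rows(enumerate(reader, start=2), str(path))


def default_patterns() -> PatternRepository:
    """The six template→predicate mappings vendored with the package."""
    text = (
        resources.files("ontomine").joinpath("data/patterns.tsv").read_text("utf-8")
    )
    reader = csv.DictReader(text.splitlines(), delimiter="\t")
    return _parse_rows(enumerate(reader, start=2), "default patterns")


def _concept_keys(concepts: list[EnrichedConcept]):
    """(surface-key → concept, stem-key → concept) lookup maps.

    Surface keys cover the discovered surface, the preferred label and all
    synonyms; stem keys are the Porter-stemmed token sequences of the same,
    giving the inflection fallback.
    """
    by_surface: dict[str, EnrichedConcept] = {}
    by_stem: dict[str, EnrichedConcept] = {}
    for concept in sorted(concepts, key=lambda c: c.surface_key):
        names = [concept.surface]
        if concept.pref_label:
            names.append(concept.pref_label)
        names.extend(concept.alt_labels)
        for name in names:
            skey = normalize_text(name)
            if skey and skey not in by_surface:
                by_surface[skey] = concept
            stem_key = " ".join(porter.stem(tok) for tok in skey.split())
            if stem_key and stem_key not in by_stem:
                by_stem[stem_key] = concept
    return by_surface, by_stem


def _literal_matches(tokens, pos: int, literal: list[str]) -> bool:
    if pos + len(literal) > len(tokens):
        return False
    for offset, lit in enumerate(literal):
        tok = tokens[pos + offset]
        if tok.surface.lower() != lit and tok.stem != porter.stem(lit):
            return False
    return True


def match_sentence(
    sentence: Sentence,
    concepts: list[EnrichedConcept],
    repo: PatternRepository,
) -> list[TripleCandidate]:
    """All pattern instantiations found in one sentence.

    Slot gaps must be maximal concept mentions adjacent to the pattern's
    literal tokens; when the written text is a synonym rather than the
    discovered surface, the synonym resolves to the same concept. Matching
    is insensitive to letter case. Emitted candidates carry
    ``pattern_matched`` provenance and a zero relatedness score.
    """
    if not sentence.tokens:
        sentence = analyze(sentence)
    tokens = [t for t in sentence.tokens if t.pos != "."]

    by_surface, by_stem = _concept_keys(concepts)

    def resolve(start: int, end: int) -> EnrichedConcept | None:
        words = tokens[start:end]
        if not words or len(words) > _MAX_SLOT_TOKENS:
            return None
        skey = normalize_text(" ".join(t.surface for t in words))
        hit = by_surface.get(skey)
        if hit is not None:
            return hit
        return by_stem.get(" ".join(t.stem for t in words))

    results: list[TripleCandidate] = []
    seen: set[tuple] = set()
    n = len(tokens)

    for pat in repo:
        lit0, lit1, lit2, x_first = pat.parts()
        # positions where the leading literal can sit
        starts = (
            [i for i in range(n) if _literal_matches(tokens, i, lit0)]
            if lit0
            else [None]
        )
        for i0 in starts:
            gap1_start_min = (i0 + len(lit0)) if i0 is not None else 0
            # candidate positions of the middle literal
            for p1 in range(gap1_start_min + 1, n):
                if not _literal_matches(tokens, p1, lit1):
                    continue
                # first slot: maximal resolving gap ending right before lit1
                gap1_lo = gap1_start_min if i0 is not None else max(
                    0, p1 - _MAX_SLOT_TOKENS
                )
                first = None
                for a in range(gap1_lo, p1):
                    if i0 is not None and a != gap1_start_min:
                        break
                    cand = resolve(a, p1)
                    if cand is not None:
                        first = cand
                        break
                if i0 is not None and first is None:
                    # fixed-start gap did not resolve
                    continue
                if first is None:
                    continue
                gap2_start = p1 + len(lit1)
                second = None
                if lit2:
                    for p2 in range(gap2_start + 1, n - len(lit2) + 1):
                        if not _literal_matches(tokens, p2, lit2):
                            continue
                        cand = resolve(gap2_start, p2)
                        if cand is not None:
                            second = cand
                            break
                else:
                    # maximal gap running to the right
                    for end in range(
                        min(n, gap2_start + _MAX_SLOT_TOKENS), gap2_start, -1
                    ):
                        cand = resolve(gap2_start, end)
                        if cand is not None:
                            second = cand
                            break
                if second is None or second is first:
                    continue
                x_concept, y_concept = (
                    (first, second) if x_first else (second, first)
                )
                key = (x_concept.surface_key, pat.predicate, y_concept.surface_key)
                if key in seen:
                    continue
                seen.add(key)
                results.append(
                    TripleCandidate(
                        subject=x_concept,
                        predicate=pat.predicate,
                        object=y_concept,
                        score=_ZERO,
                        provenance="pattern_matched",
                    )
                )
    return results
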