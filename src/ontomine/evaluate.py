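"""Precision / recall / F-measure scoring against gold-standard sets.

Three granularities share the same set arithmetic: concept surfaces
(normalized strings), directed hierarchy pairs (child, parent), and full
(subject, predicate, object) triples with predicate equality by IRI. The
F-measure is the harmonic mean 2·p·r/(p+r), defined as 0 when both
precision and recall vanish.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from .textproc import normalize_text

__all__ = [
    "GoldStandard",
    "EvalReport",
    "score_concepts",
    "score_hierarchy",
    "score_non_hierarchy",
]


@dataclass
class GoldStandard:
    concepts: set[str] = field(default_factory=set)
    hierarchy_pairs: set[tuple[str, str]] = field(default_factory=set)
    non_hierarchy_triples: set[tuple[str, str, str]] = field(default_factory=set)

    @classmethod
    def load(
        cls,
        concepts_path: str | Path | None = None,
        hierarchy_path: str | Path | None = None,
        triples_path: str | Path | None = None,
    ) -> "GoldStandard":
        """Concepts: one per line. Pairs/triples: TSV rows."""
        gold = cls()
        if concepts_path:
            with open(concepts_path, encoding="utf-8") as fh:
                gold.concepts = {
                    normalize_text(line) for line in fh if line.strip()
                }
        if hierarchy_path:
            with open(hierarchy_path, encoding="utf-8", newline="") as fh:
                for row in csv.reader(fh, delimiter="\t"):
                    if len(row) >= 2:
                        gold.hierarchy_pairs.add(
                            (normalize_text(row[0]), normalize_text(row[1]))
                        )
        if triples_path:
            with open(triples_path, encoding="utf-8", newline="") as fh:
                for row in csv.reader(fh, delimiter="\t"):
                    if len(row) >= 3:
                        gold.non_hierarchy_triples.add(
                            (
                                normalize_text(row[0]),
                                row[1].strip(),
                                normalize_text(row[2]),
                            )
                        )
        return gold


@dataclass(frozen=True)
class EvalReport:
    precision: float
    recall: float
    f_measure: float
    tp: int
    fp: int
    fn: int

    @classmethod
    def from_sets(cls, predicted: set, gold: set) -> "EvalReport":
        if not gold:
            raise ValueError("gold standard is empty; recall undefined")
        tp = len(predicted & gold)
        fp = len(predicted - gold)
        fn = len(gold - predicted)
        if not predicted:
            warnings.warn("empty prediction set; precision defined as 0",
                          stacklevel=3)
            precision = 0.0
        else:
            precision = tp / len(predicted)
        recall = tp / len(gold)
        f = (
            2 * precision * recall / (precision + recall)
            if precision + recall > 0
            else 0.0
        )
        return cls(precision=precision, recall=recall, f_measure=f,
                   tp=tp, fp=fp, fn=fn)

    def as_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f_measure": self.f_measure,
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2))

    def __str__(self) -> str:
        return (
            f"P={self.precision:.4f} R={self.recall:.4f} "
            f"F={self.f_measure:.4f} (tp={self.tp} fp={self.fp} fn={self.fn})"
        )


def score_concepts(predicted: set[str], gold: set[str]) -> EvalReport:
    """Score concept extraction over normalized surface strings."""
    return EvalReport.from_sets(
        {normalize_text(s) for s in predicted},
        {normalize_text(s) for s in gold},
    )


def score_hierarchy(
    predicted_pairs: set[tuple[str, str]], gold_pairs: set[tuple[str, str]]
) -> EvalReport:
    """Score directed (child, parent) hierarchy pair extraction."""
    return EvalReport.from_sets(set(predicted_pairs), set(gold_pairs))


def score_non_hierarchy(
    predicted_triples: set[tuple[str, str, str]],
    gold_triples: set[tuple[str, str, str]],
) -> EvalReport:
    """Score (subject, predicate, object) triple extraction; predicates
    compare by IRI string equality."""
    return EvalReport.from_sets(set(predicted_triples), set(gold_triples))
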