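"""Precision/recall/F scoring of identified vs annotated isoforms.

Scoring follows a three-level scheme.  At the *nucleotide* level each
identified isoform is matched to the annotated isoform sharing the most
nucleotides; identified isoforms are ranked by overlap percentage and, when
there are more identified than annotated isoforms, only the top ones are
paired (the rest are false positives with zero precision).  Per-isoform
precision is shared nucleotides over identified nucleotides; recall is the
symmetric construction on the annotated side.  Gene-level precision/recall
are the means over identified/annotated isoforms and F is their harmonic
mean (zero when either rate is zero).

At the *exon* level an identified exon and an annotated exon "overlap"
when the identified exon covers at least 50 % of the annotated exon;
per-isoform rates count overlapping exons.  At the *transcript* level two
isoforms are "matched" when every exon is matched one-to-one in order by
the 50 % rule, and rates are the matched fractions on each side.

Pairing is greedy without replacement on the ranked list; ties break by
input order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

from .gene_model import GeneModel, Isoform

__all__ = [
    "GeneEvaluation",
    "match_pairs",
    "evaluate_nucleotide",
    "evaluate_exon",
    "evaluate_transcript",
    "evaluate_all_levels",
]


@dataclass(frozen=True)
class GeneEvaluation:
    level: str
    precision: float
    recall: float
    f_score: float

    @classmethod
    def from_rates(cls, level: str, precision: float, recall: float) -> "GeneEvaluation":
        if precision > 0 and recall > 0:
            f = 2.0 / (1.0 / precision + 1.0 / recall)
        else:
            f = 0.0
        return cls(level, precision, recall, f)


def _intervals(iso: Isoform, gene: GeneModel) -> list[tuple[int, int]]:
    return [(gene.subexons[i - 1].start, gene.subexons[i - 1].end) for i in iso.included]


def _shared_nucleotides(a: Isoform, b: Isoform, gene: GeneModel) -> int:
    # subexons are disjoint, so shared bases = total length of co-included subexons
    common = set(a.included) & set(b.included)
    return sum(gene.subexons[i - 1].length for i in common)


def _exons_overlap(identified_exon: tuple[int, int], annotated_exon: tuple[int, int]) -> bool:
    """50 % rule: the identified exon covers at least half of the annotated exon."""
    s = max(identified_exon[0], annotated_exon[0])
    e = min(identified_exon[1], annotated_exon[1])
    inter = max(0, e - s)
    return inter * 2 >= (annotated_exon[1] - annotated_exon[0])


def match_pairs(
    identified: Sequence[Isoform],
    annotated: Sequence[Isoform],
    overlap_fn: Callable[[Isoform, Isoform], tuple[float, float]],
) -> list[tuple[int, int, float]]:
    """Rank-and-pair identified isoforms against annotated isoforms.

    ``overlap_fn(a, b)`` returns ``(percentage, raw_overlap)`` where the
    percentage (overlap relative to the identified isoform) orders the
    pairing.  Each identified isoform is first matched to its best-overlap
    annotated isoform; identified isoforms are then processed in descending
    percentage order and greedily paired with their best still-unclaimed
    annotated isoform, at most ``min(k, r)`` pairs in total.  Returns
    ``(identified index, annotated index, percentage)`` triples.
    """
    if not identified or not annotated:
        return []
    best = []
    for i, iso in enumerate(identified):
        scores = [overlap_fn(iso, ann) for ann in annotated]
        top = max(range(len(annotated)), key=lambda j: scores[j][0])
        best.append((i, scores[top][0], scores))
    order = sorted(best, key=lambda rec: -rec[1])
    claimed: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    for i, _, scores in order:
        if len(pairs) >= len(annotated):
            break
        free = [j for j in range(len(annotated)) if j not in claimed]
        if not free:
            break
        j = max(free, key=lambda j: scores[j][0])
        claimed.add(j)
        pairs.append((i, j, scores[j][0]))
    return pairs


def _mean(values: Sequence[float]) -> float:
    return sum(values) / len(values) if values else 0.0


def _paired_rates(
    identified: Sequence[Isoform],
    annotated: Sequence[Isoform],
    pct_fn: Callable[[Isoform, Isoform], float],
) -> float:
    """Mean per-isoform rate on the identified side; unpaired isoforms score 0."""
    if not identified:
        return 0.0
    pairs = match_pairs(
        identified, annotated, lambda a, b: (pct_fn(a, b), pct_fn(a, b))
    )
    rate = {i: pct for i, _, pct in pairs}
    return _mean([rate.get(i, 0.0) for i in range(len(identified))])


def evaluate_nucleotide(
    identified: Sequence[Isoform], annotated: Sequence[Isoform], gene: GeneModel
) -> GeneEvaluation:
    """Nucleotide-level precision/recall/F for one gene."""

    def precision_pct(ident: Isoform, ann: Isoform) -> float:
        return _shared_nucleotides(ident, ann, gene) / ident.spliced_length(gene)

    def recall_pct(ann: Isoform, ident: Isoform) -> float:
        return _shared_nucleotides(ann, ident, gene) / ann.spliced_length(gene)

    precision = _paired_rates(identified, annotated, precision_pct)
    recall = _paired_rates(annotated, identified, recall_pct)
    return GeneEvaluation.from_rates("nucleotide", precision, recall)


def evaluate_exon(
    identified: Sequence[Isoform], annotated: Sequence[Isoform], gene: GeneModel
) -> GeneEvaluation:
    """Exon-level rates under the 50 %-coverage overlap rule."""

    def precision_pct(ident: Isoform, ann: Isoform) -> float:
        iex, aex = ident.exons(gene), ann.exons(gene)
        hit = sum(1 for e in iex if any(_exons_overlap(e, f) for f in aex))
        return hit / len(iex)

    def recall_pct(ann: Isoform, ident: Isoform) -> float:
        iex, aex = ident.exons(gene), ann.exons(gene)
        hit = sum(1 for f in aex if any(_exons_overlap(e, f) for e in iex))
        return hit / len(aex)

    precision = _paired_rates(identified, annotated, precision_pct)
    recall = _paired_rates(annotated, identified, recall_pct)
    return GeneEvaluation.from_rates("exon", precision, recall)


def _transcripts_matched(ident: Isoform, ann: Isoform, gene: GeneModel) -> bool:
    """Every exon matched one-to-one in order by the 50 % rule."""
    iex, aex = ident.exons(gene), ann.exons(gene)
    if len(iex) != len(aex):
        return False
    # every aligned exon pair must satisfy the 50 % rule in both roles,
    # which keeps the matched relation symmetric
    return all(
        _exons_overlap(e, f) and _exons_overlap(f, e) for e, f in zip(iex, aex)
    )


def evaluate_transcript(
    identified: Sequence[Isoform], annotated: Sequence[Isoform], gene: GeneModel
) -> GeneEvaluation:
    """Transcript-level rates: fractions of exactly matched isoforms."""
    if not identified or not annotated:
        return GeneEvaluation.from_rates("transcript", 0.0, 0.0)
    pairs = match_pairs(
        identified,
        annotated,
        lambda a, b: (1.0 if _transcripts_matched(a, b, gene) else 0.0,) * 2,
    )
    matched = sum(1 for _, _, pct in pairs if pct >= 1.0)
    precision = matched / len(identified)
    recall = matched / len(annotated)
    return GeneEvaluation.from_rates("transcript", precision, recall)


def evaluate_all_levels(
    identified: Sequence[Isoform], annotated: Sequence[Isoform], gene: GeneModel
) -> list[GeneEvaluation]:
    return [
        evaluate_nucleotide(identified, annotated, gene),
        evaluate_exon(identified, annotated, gene),
        evaluate_transcript(identified, annotated, gene),
    ]
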