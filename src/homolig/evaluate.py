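"""Desk-scale evaluation machinery: overlap, rank sensitivity, jackknife.

A predicted site matches a gold annotation when it covers at least 50 % of
the annotated residues.  Rank sensitivity at k is the fraction of queries
with a matching cluster at rank <= k; queries with a single predicted
cluster count at rank 1.  The jackknife filter removes the query itself and
(near-)identical homologs before clustering, so inference quality can be
measured without the answer leaking in.
"""

from __future__ import annotations

from dataclasses import dataclass

from .align import PairwiseAlignment


@dataclass(frozen=True)
class GoldAnnotation:
    query_id: str
    residues: frozenset[int]
    label: str = "site"


def load_gold_tsv(path) -> list[GoldAnnotation]:
    """BED-like TSV: query id, residue number, label."""
    groups: dict[tuple[str, str], set[int]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            qid, num = fields[0], int(fields[1])
            label = fields[2] if len(fields) > 2 else "site"
            groups.setdefault((qid, label), set()).add(num)
    return [GoldAnnotation(q, frozenset(res), lab)
            for (q, lab), res in sorted(groups.items())]


def site_overlap(predicted: set[int], gold: set[int],
                 denominator: str = "gold") -> float:
    """Fraction of the gold annotation covered by the prediction.

    ``denominator='gold'`` (default) is |pred & gold| / |gold|;
    ``'jaccard'`` uses the union instead.  A fraction >= 0.5 counts as a
    match.
    """
    if not gold:
        raise ValueError("gold residue set must be non-empty")
    if not predicted:
        raise ValueError("predicted residue set must be non-empty")
    inter = len(set(predicted) & set(gold))
    if denominator == "gold":
        return inter / len(gold)
    if denominator == "jaccard":
        return inter / len(set(predicted) | set(gold))
    raise ValueError(f"unknown denominator {denominator!r}")


def is_match(predicted: set[int], gold: set[int], threshold: float = 0.5,
             denominator: str = "gold") -> bool:
    return site_overlap(predicted, gold, denominator) >= threshold


def rank_sensitivity(predictions: dict[str, list[set[int]]],
                     gold: dict[str, set[int]], k: int,
                     threshold: float = 0.5) -> float:
    """Fraction of queries with a matching cluster at rank <= k.

    ``predictions[qid]`` is the ranked list of predicted residue sets for
    that query (best first).  Queries with exactly one predicted cluster are
    by construction evaluated at rank 1.
    """
    if not predictions:
        return 0.0
    hits = 0
    for qid, ranked in predictions.items():
        gold_set = gold.get(qid)
        if not gold_set:
            continue
        for site in ranked[:k]:
            if site and is_match(site, gold_set, threshold):
                hits += 1
                break
    return hits / len(predictions)


def jackknife_filter(alignments: list[PairwiseAlignment], query_id: str,
                     max_identity: float = 1.0) -> list[PairwiseAlignment]:
    """Drop the query itself and neighbors too close to it.

    With the default ceiling of 1.0 only exact (100 %) matches are dropped;
    a stricter ceiling c < 1 retains neighbors at identity <= c (so a
    neighbor at exactly the ceiling is kept, one above it is dropped).
    """
    kept = []
    for aln in alignments:
        if aln.neighbor_id == query_id:
            continue
        ident = aln.percent_identity
        if ident >= 1.0:
            continue
        if ident > max_identity:
            continue
        kept.append(aln)
    return kept
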