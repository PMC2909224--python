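"""Biological-relevance scoring and ranking of binding-site clusters.

Four raw terms are computed per cluster and combined as Z-scores across the
query's scored clusters:

* conservation — mean per-column (1 - H/ln 20) of the cluster's binding-site
  multiple alignment, Shannon entropy H over Henikoff-Henikoff weighted
  residue frequencies;
* PSSM score — the query's aligned binding-site residues summed against a
  Gribskov-style profile (column score = frequency-weighted mix of
  substitution-matrix rows, which carries the implicit pseudo-counts);
* contact count — mean total atom-pair contacts of the member sites;
* identity — mean whole-alignment sequence identity of members to the query.

Clusters with a single non-redundant member (after collapsing members above
90 % mutual identity) are *singletons*: unscored, ranked after every scored
cluster.  Clusters whose members all bind listed non-biological compounds
are dropped from the ranked list entirely (flagged in the report).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import matrix as _matrix
from .errors import FrameError

GAP = "-"


@dataclass
class SiteAlignment:
    """A cluster's binding-site multiple alignment in query numbering.

    ``rows[m][c]`` is member m's residue at column c (``-`` when the
    member's alignment does not cover that query position);
    ``full_rows`` are the complete aligned member sequences used for
    Henikoff weighting.
    """

    columns: list[int]                 # query residue numbers
    member_ids: list[str]
    rows: list[str]
    full_rows: list[str] | None = None

    def __post_init__(self):
        for row in self.rows:
            if len(row) != len(self.columns):
                raise FrameError("site-alignment row length != column count")


def henikoff_weights(sequences: list[str]) -> np.ndarray:
    """Position-based sequence weights, normalized to sum to 1.

    Each column contributes 1/(r*s) to a member, where r is the number of
    distinct symbols in the column and s the number of members sharing that
    member's symbol.  The gap character counts as a symbol of its own.
    """
    if not sequences:
        raise ValueError("need at least one sequence")
    length = len(sequences[0])
    if length == 0 or any(len(s) != length for s in sequences):
        raise ValueError("sequences must be non-empty and equal-length")
    n = len(sequences)
    weights = np.zeros(n)
    for c in range(length):
        column = [s[c] for s in sequences]
        counts: dict[str, int] = {}
        for sym in column:
            counts[sym] = counts.get(sym, 0) + 1
        r = len(counts)
        for m, sym in enumerate(column):
            weights[m] += 1.0 / (r * counts[sym])
    total = weights.sum()
    return weights / total


def _column_frequencies(column: list[str], weights: np.ndarray) -> dict[str, float]:
    """Weighted residue frequencies over the non-gap members of a column."""
    freq: dict[str, float] = {}
    total = 0.0
    for sym, w in zip(column, weights):
        if sym == GAP:
            continue
        freq[sym] = freq.get(sym, 0.0) + w
        total += w
    if total > 0:
        for sym in freq:
            freq[sym] /= total
    return freq


def conservation_entropy(alignment: SiteAlignment, weights: np.ndarray) -> float:
    """Mean over columns of 1 - H/ln 20 (H = weighted Shannon entropy).

    All-gap columns are skipped; a fully conserved alignment scores 1 and a
    column uniform over the 20 residues contributes 0.
    """
    values = []
    for c in range(len(alignment.columns)):
        column = [row[c] for row in alignment.rows]
        freq = _column_frequencies(column, weights)
        if not freq:
            continue
        h = -sum(p * math.log(p) for p in freq.values() if p > 0)
        values.append(1.0 - h / math.log(20))
    if not values:
        return 0.0
    return float(np.mean(values))


def build_pssm(alignment: SiteAlignment, weights: np.ndarray,
               matrix=None) -> np.ndarray:
    """Gribskov profile: score(p, a) = sum_b f_p(b) * M(a, b).

    Returns an array of shape (n_columns, 20) over the standard amino-acid
    alphabet in ``PSSM_ALPHABET`` order.  Averaging matrix rows by the
    observed weighted frequencies is the implicit pseudo-count: unseen
    residues still score through their similarity to the observed ones.
    """
    matrix = matrix if matrix is not None else _matrix.load_matrix()
    pssm = np.zeros((len(alignment.columns), len(PSSM_ALPHABET)))
    for c in range(len(alignment.columns)):
        column = [row[c] for row in alignment.rows]
        freq = _column_frequencies(column, weights)
        for ai, a in enumerate(PSSM_ALPHABET):
            pssm[c, ai] = sum(f * _matrix.lookup(matrix, a, b)
                              for b, f in freq.items())
    return pssm


PSSM_ALPHABET = "ARNDCQEGHILKMFPSTWYV"
_AA_INDEX = {a: i for i, a in enumerate(PSSM_ALPHABET)}


def pssm_score_query(pssm: np.ndarray, query_residues: list[str],
                     gap_mode: str = "column_min") -> float:
    """Sum per-column PSSM scores of the query residues.

    ``query_residues[c]`` is the query's one-letter code at column c, or the
    gap character when the query has no residue there; gapped columns score
    the column minimum by default (``gap_mode='zero'`` scores 0).
    """
    if len(query_residues) != pssm.shape[0]:
        raise FrameError("query residue list does not match PSSM columns")
    total = 0.0
    for c, aa in enumerate(query_residues):
        if aa == GAP:
            if gap_mode == "column_min":
                total += float(pssm[c].min())
            continue
        idx = _AA_INDEX.get(aa.upper())
        if idx is None:          # non-standard query residue: average row
            total += float(pssm[c].mean())
        else:
            total += float(pssm[c, idx])
    return total


def avg_interfacial_contacts(total_contacts: list[int]) -> float:
    """Mean number of atom-pair contacts over the member sites."""
    return float(np.mean(total_contacts))


def avg_identity_to_query(identities: list[float]) -> float:
    """Mean whole-alignment identity (fraction) of members to the query."""
    return float(np.mean(identities))


def nonredundant_count(member_rows: list[str],
                       redundancy_cutoff: float = 0.90) -> int:
    """Representatives left after greedily collapsing members whose mutual
    identity exceeds the cutoff (computed over positions where both are
    non-gap; members with no comparable position count as distinct)."""
    reps: list[str] = []
    for row in member_rows:
        redundant = False
        for rep in reps:
            both = [(a, b) for a, b in zip(row, rep) if a != GAP and b != GAP]
            if both:
                ident = sum(a == b for a, b in both) / len(both)
                if ident > redundancy_cutoff:
                    redundant = True
                    break
        if not redundant:
            reps.append(row)
    return len(reps)


def is_singleton(member_rows: list[str], redundancy_cutoff: float = 0.90) -> bool:
    return nonredundant_count(member_rows, redundancy_cutoff) <= 1


@dataclass
class ClusterScore:
    cluster_id: str
    member_ids: list[str]
    ligand_codes: list[str]
    query_positions: list[int]
    conservation: float = 0.0
    pssm_score: float = 0.0
    avg_contacts: float = 0.0
    avg_identity: float = 0.0
    singleton: bool = False
    nonbiological: bool = False
    z: tuple[float, float, float, float] | None = None
    combined: float | None = None
    rank: int | None = None


@dataclass
class RankedAnnotation:
    query_id: str
    ranked: list[ClusterScore]         # scored clusters, best first, then singletons
    excluded: list[ClusterScore]       # all-non-biological clusters


def _zscores(values: np.ndarray) -> np.ndarray:
    """(x - mean)/sd with sample (n-1) sd; a zero or undefined sd gives 0."""
    n = len(values)
    if n < 2:
        return np.zeros(n)
    sd = values.std(ddof=1)
    if sd == 0:
        return np.zeros(n)
    return (values - values.mean()) / sd


def rank_clusters(scores: list[ClusterScore],
                  weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0),
                  query_id: str = "query") -> RankedAnnotation:
    """Z-score the four raw terms across scored clusters and rank.

    Non-biological clusters are removed first (kept in ``excluded``);
    singletons receive no score and rank after every scored cluster, in
    input order.  Ordering among scored clusters is by combined score
    descending, ties by cluster id for determinism.
    """
    if not scores:
        raise ValueError("need at least one cluster")
    excluded = [s for s in scores if s.nonbiological]
    eligible = [s for s in scores if not s.nonbiological]
    scored = [s for s in eligible if not s.singleton]
    singletons = [s for s in eligible if s.singleton]

    if scored:
        terms = np.array([[s.conservation, s.pssm_score,
                           s.avg_contacts, s.avg_identity] for s in scored])
        z = np.column_stack([_zscores(terms[:, j]) for j in range(4)])
        w = np.asarray(weights, dtype=float)
        combined = z @ w
        for s, zrow, comb in zip(scored, z, combined):
            s.z = tuple(float(v) for v in zrow)
            s.combined = float(comb)
        scored.sort(key=lambda s: (-s.combined, s.cluster_id))
    ranked = scored + singletons
    for i, s in enumerate(ranked):
        s.rank = i + 1
    for s in excluded:
        s.rank = None
    return RankedAnnotation(query_id, ranked, excluded)
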