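"""Binding-site similarity: BLOSUM62 score, bit conversion, conservation score.

Two sites are compared over the gapped alignment induced by composing their
neighbors' query alignments.  An aligned position scores the BLOSUM62 value
of the two residues plus a +1 bonus when the position is structurally
equivalent; a position present in one site but unaligned in the other
scores the gap penalty w = -4 (the most unfavorable BLOSUM62 substitution).
Raw scores convert to bits with the ungapped BLOSUM62 statistical
parameters (lambda = 0.3176 nats, K = 0.134) and the *conservation score*
CS normalizes by the larger of the two self bit scores, clamped to [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

from . import matrix as _matrix
from .align import ComposedAlignment
from .errors import DegenerateSiteError
from .structure import BindingSite

SiteResidues = Mapping[int, str]       # residue number -> one-letter code


@dataclass
class ScoringParams:
    matrix: object = None              # Bio substitution matrix Array
    theta: float = 1.0                 # structural-equivalence bonus
    gap_penalty: float = -4.0
    lambda_: float = 0.3176            # nats per raw-score unit
    K: float = 0.134
    span: str = "union"                # positions summed: union|intersection

    def __post_init__(self):
        if self.matrix is None:
            self.matrix = _matrix.load_matrix()
        if self.lambda_ <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")
        if self.span not in ("union", "intersection"):
            raise ValueError(f"unknown span {self.span!r}")


@dataclass(frozen=True)
class SitePairScore:
    raw: float
    bits: float
    cs: float


def _site_map(site) -> dict[int, str]:
    if isinstance(site, BindingSite):
        return {n: aa for n, aa in site.residues}
    return dict(site)


def position_score(aa_i: str, aa_j: str, aligned: bool, equivalent: bool,
                   params: ScoringParams) -> float:
    """Score of one alignment position: H(i,j) (+theta if structurally
    equivalent) when aligned, the gap penalty otherwise."""
    if not aligned:
        return params.gap_penalty
    score = _matrix.lookup(params.matrix, aa_i, aa_j)
    if equivalent:
        score += params.theta
    return score


def raw_site_score(site_a, site_b, composed: ComposedAlignment,
                   params: ScoringParams) -> float:
    """Sum of position scores over the two sites' gapped alignment.

    A position is *aligned* when the composed alignment pairs a site residue
    of one site with a site residue of the other; those positions score
    through the matrix (+theta when structurally equivalent).  With
    ``span='union'`` (default) every remaining site residue — unaligned, or
    aligned to a chain position outside the other binding site — scores the
    gap penalty once.  ``span='intersection'`` drops the gap terms and sums
    the aligned positions only.  Positions held by neither site never enter
    the sum.
    """
    a_res = _site_map(site_a)
    b_res = _site_map(site_b)
    total = 0.0
    matched_a: set[int] = set()
    matched_b: set[int] = set()
    for pair in composed.pairs:
        if pair.a_res in a_res and pair.b_res in b_res:
            total += position_score(pair.a_aa, pair.b_aa, True,
                                    pair.equivalent, params)
            matched_a.add(pair.a_res)
            matched_b.add(pair.b_res)
    if params.span == "union":
        total += params.gap_penalty * (len(a_res) - len(matched_a))
        total += params.gap_penalty * (len(b_res) - len(matched_b))
    return total


def self_raw_score(site, params: ScoringParams) -> float:
    """Score of a site against itself: identity alignment, every position
    aligned and structurally equivalent."""
    return sum(position_score(aa, aa, True, True, params)
               for aa in _site_map(site).values())


def bit_score(raw: float, params: ScoringParams) -> float:
    """bits = (lambda * raw - ln K) / ln 2."""
    return (params.lambda_ * raw - math.log(params.K)) / math.log(2)


def conservation_score_cs(site_a, site_b, composed: ComposedAlignment,
                          params: ScoringParams) -> SitePairScore:
    """CS = bits(a,b) / max(bits(a,a), bits(b,b)), clamped to [0, 1].

    The max in the denominator makes CS symmetric; a site scored against
    itself gets exactly 1.  Sites whose self bit score is non-positive
    cannot be normalized and raise :class:`DegenerateSiteError`.
    """
    self_a = bit_score(self_raw_score(site_a, params), params)
    self_b = bit_score(self_raw_score(site_b, params), params)
    denom = max(self_a, self_b)
    if denom <= 0:
        raise DegenerateSiteError("site self bit score is non-positive")
    raw = raw_site_score(site_a, site_b, composed, params)
    bits = bit_score(raw, params)
    cs = min(1.0, max(0.0, bits / denom))
    return SitePairScore(raw=raw, bits=bits, cs=cs)
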