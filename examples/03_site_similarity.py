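"""Score a pair of binding sites: raw score, bit score, conservation score.

Walks through the similarity arithmetic on a three-residue toy site "ACD":
aligned identical positions score the BLOSUM62 diagonal plus the +1
structural-equivalence bonus; a position missing from one site scores the
gap penalty -4.  Raw scores convert to bits with the ungapped BLOSUM62
parameters (lambda = 0.3176, K = 0.134), and the conservation score CS
divides by the larger self bit score, giving a value in [0, 1]: 1 for a
site against itself, 0 for unrelated sites.
"""

from homolig import ScoringParams, bit_score, conservation_score_cs, raw_site_score
from homolig.align import ComposedAlignment, ComposedPair

params = ScoringParams()

site = {1: "A", 2: "C", 3: "D"}
identity = ComposedAlignment("A", "A", "Q",
                             [ComposedPair(n, n, aa, aa, True)
                              for n, aa in site.items()])
raw = raw_site_score(site, site, identity, params)
print(f"'ACD' against itself: raw = {raw:.0f}  "
      f"(BLOSUM62 diagonal 4+9+6 plus three +1 bonuses)")
print(f"  bits = {bit_score(raw, params):.3f}, "
      f"CS = {conservation_score_cs(site, site, identity, params).cs:.3f}")

truncated = {1: "A", 2: "C"}
raw2 = raw_site_score(site, truncated, identity, params)
score2 = conservation_score_cs(site, truncated, identity, params)
print(f"\n'ACD' against 'AC-': raw = {raw2:.0f}  "
      f"(third position gapped: (4+1)+(9+1)-4)")
print(f"  bits = {score2.bits:.3f}, CS = {score2.cs:.3f}")

far = {11: "A", 12: "C", 13: "D"}
score3 = conservation_score_cs(site, far, ComposedAlignment("A", "B", "Q", []),
                               params)
print(f"\ndisjoint sites: raw = {score3.raw:.0f} (all gaps), "
      f"CS clamps to {score3.cs:.1f}")
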