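# Methods

`homolig` annotates protein–small-molecule binding sites on a query protein
by transferring, clustering and ranking the sites observed in the crystal
structures of its homologs. This note records the model, the parameters
that matter, and the design choices made where the design was genuinely
open.

## Observed binding sites

A binding site is the set of residues on one protein chain having at least
one heavy atom within **4.0 Å** (inclusive) of any heavy atom of a bound
small molecule; 4.0 Å is roughly the sum of van der Waals radii plus ~0.5 Å
tolerance for coordinate error. Sites with fewer than **5** residues are
discarded. When a molecule touches several chains, the site is assigned to
a single chain only if that chain holds at least **75 %** of all atom-pair
contacts; otherwise one site per contacting chain is emitted (each still
subject to the 5-residue floor).

Parsing conventions (the file formats do not force a choice, so one is
fixed here): hydrogens are dropped on read; waters are never ligands; only
the first model of a multi-model entry is used; alternate locations resolve
to the highest occupancy, ties to the first listed. Chemically modified
residues indexed inside a polymer chain are treated as polymer, not as
ligands. Residues are identified by author numbering throughout.

A heteroatom group qualifies as a candidate small molecule when it has at
least **5 heavy atoms** and a molecular weight inside **70–800 Da** (both
boundaries inclusive; the file formats carry no MW, so it is computed from
standard atomic masses). Lone single-atom species (metal ions etc.) are
rejected. Separately, a curated plain-text list of common crystallization
additives (glycerol, ethylene glycol, PEG fragments, MES/HEPES, sulfate,
…) marks compounds as *non-biological*; this flag does not block site
extraction but later removes clusters composed solely of such compounds
from the ranking. The shipped list is a starting point and is meant to be
replaced by the user's own.

## Transfer through precomputed alignments

Structure superposition is upstream of this package: the inputs are
residue-level query↔neighbor alignments with a per-position
structural-equivalence flag (TSV or gapped-FASTA; when the flag is absent
all aligned positions are treated as equivalent, the inputs being
structure-derived). A neighbor is admitted at **≥ 30 %** sequence identity,
computed over the aligned (superimposed) positions only.

Neighbor-to-neighbor correspondence is obtained by *composing through the
query*: (A→query) ∘ (query→B). Two neighbors may align more extensively to
each other directly than either does to the query; composing through the
query restricts the comparison to the region that matters for annotation.
The equivalence flag of a composed pair is the AND of the two legs.

A neighbor site transfers to the query only if at least **75 %** of its
contacts fall on alignment-covered residues. "Contacts" here is counted in
atom-pair contacts by default (`footprint_mode="pairs"`), consistent with
the contact-count term used later in ranking; a `"residues"` mode counting
distinct residues is provided, since either reading of the rule is
defensible.

## Site similarity (conservation score)

Two sites are compared over the gapped alignment induced by their composed
alignment. A position where a site residue of A is aligned to a site
residue of B scores the BLOSUM62 value of the two residues, **+1** when
the position is structurally equivalent. Every remaining site residue —
unaligned, or aligned to a chain position outside the other site — scores
the gap penalty **w = −4**, the most unfavorable BLOSUM62 substitution.
Positions held by neither site contribute nothing. (A broader reading
would score any alignment-covered position through the matrix even when
only one site holds it; that makes disjoint pockets on near-identical
homologs look similar, so the stricter site-against-site reading is used.
The summation span is configurable: `span="union"` with gap penalties, or
`"intersection"` without.)

The raw score converts to bits,

    bits = (λ·raw − ln K) / ln 2,

with the ungapped BLOSUM62 parameters **λ = 0.3176** (nats) and
**K = 0.134** as defaults — the original statistical parameters are not
recoverable, so the standard ungapped values are used and both are
configurable. The conservation score is

    CS(a, b) = bits(a, b) / max(bits(a, a), bits(b, b)),

clamped to [0, 1]; the max in the denominator makes CS symmetric, a site
against itself scores exactly 1, and a site whose self bit score is
non-positive cannot be normalized (degenerate-site error).

## Clustering and the free-energy cutoff

Sites are clustered by complete linkage on d = 1 − CS (complete linkage:
cluster distance = max member-pair distance). The agglomeration is
deterministic: clusters carry creation indices and exact ties in the merge
distance break on the lowest index pair. The dendrogram is cut at the
height minimizing

    F = − Σ_C (|C|/N) · mean pairwise bit score within C
        + T · Σ_C (|C|/N) · ln(N/|C|),

evaluated at every distinct merge height plus 0 and 1; ties prefer the
smaller cutoff. Singletons contribute zero energy, so the all-singleton
partition costs exactly T·ln N and one all-inclusive cluster costs minus
its mean similarity.

Two features of this functional form are deliberate and worth stating
because the published description leaves the algebra open:

* the energy term uses the **bit score**, not CS. Bit scores go negative
  for unrelated sites, so a cluster of unrelated sites costs energy and a
  family with no recurring pocket correctly resolves to singletons. With
  any similarity bounded below by zero, one big cluster (entropy 0, energy
  ≤ 0) would always beat the all-singleton partition (entropy T·ln N).
* the energy is **size-weighted** (|C|/N). An unweighted sum of
  per-cluster means rewards splitting a homogeneous cluster into blocks
  (each block contributes its own −mean), which makes clean recovery of
  planted partitions impossible; the size weights make the energy of a
  homogeneous cluster invariant to how the dendrogram subdivides it.

The temperature **T** balances tightness against description complexity.
The default **T = 1.0** was calibrated on the synthetic fixture suite: on
the bit scale of mid-size sites (self scores ~20–30 bits) planted
two-group partitions with within-group distance ≤ 0.1 and between-group
distance ≥ 0.9 are recovered exactly for any T in roughly (0, 19), so the
default sits far from both failure modes. It is a config value
(`temperature`), not a constant of the method.

## Ranking by biological relevance

Per cluster, four raw terms:

1. **Conservation** — mean over binding-site alignment columns of
   1 − H/ln 20, H the Shannon entropy of weighted residue frequencies.
   Member weights are Henikoff–Henikoff position-based weights computed on
   the *complete* aligned member sequences (not just site columns); the
   gap character counts as a residue type in the weight computation (a
   member absent from a region is information), while entropy frequencies
   are computed over non-gap members and renormalized. Natural log
   normalized by ln 20 makes the measure base-free.
2. **PSSM score** — a Gribskov-style profile: column score for amino acid
   a is Σ_b f(b)·BLOSUM62(a, b) with f the weighted observed frequencies;
   averaging matrix rows is the implicit pseudo-count (unseen residues
   score through their similarity to observed ones). The query's aligned
   residues are summed against the profile; query positions with no
   residue at a column score the column minimum by default
   (`pssm_gap_mode="column_min"`; `"zero"` is available).
3. **Contact count** — mean total atom-pair contacts of the member sites
   (larger interfaces rank higher).
4. **Identity** — mean whole-alignment identity of members to the query
   (not just over the site).

Each term is converted to a Z-score across the query's scored clusters
(sample n−1 standard deviation; sd = 0 → z = 0) and combined as a weighted
sum. The published coefficients were fitted empirically on data not
shipped here; the default weights are **(1, 1, 1, 1)** and a
`calibrate-weights` CLI command grid-searches alternatives on fixture
families. Clusters with one non-redundant member after collapsing members
above **90 %** mutual identity (strictly greater; greedy in input order)
are *singletons*: unscored, ranked after every scored cluster. Clusters
whose members all bind listed non-biological compounds are removed from
the ranking and flagged in the report.

## Evaluation machinery

A predicted site matches a gold annotation when it covers at least **50 %**
of the annotated residues (denominator = gold set size; a Jaccard variant
is available since the original denominator is not documented). Rank
sensitivity at k is the fraction of queries with a match at rank ≤ k;
single-cluster queries count at rank 1. The jackknife filter removes the
query itself and 100 %-identical neighbors, with an optional stricter
ceiling c (< 1) that keeps neighbors at identity ≤ c.

## Synthetic families

The fixture generator emits everything the pipeline consumes, with planted
truth: per member one PDB structure, one query↔neighbor alignment TSV, plus
a gold-annotation TSV and a JSON manifest. Geometry is a coarse extended
CA trace (3.8 Å spacing); pocket residues carry one side-chain probe atom
placed 3.0 Å from the nearest atom of a ligand positioned 9 Å off the
trace, so planted pocket residues are inside the 4.0 Å cutoff and all
others are well outside it — the contact rule needs only distances, and no
physical realism is claimed beyond that. Defaults: chains of 60 residues,
six members on an identity ladder 0.95…0.45 (mutations are planted
exactly, so realized identities match targets to rounding), an 8-residue
conserved pocket (mutation-free by default — it is the conserved signal),
a 5-residue decoy pocket mutated at rate 0.5 carried by a subset of
members, and glycerol bound at a fixed 5-residue location in half the
members to exercise the non-biological exclusion. Negative-control
families bind the ligand at disjoint per-member windows.

What passing on these fixtures does **not** show: robustness to real
structural variation (side-chain rearrangement, partial occupancy, domain
motion), to noisy or gapped structure alignments, or to the compositional
diversity of real crystallization additives. The fixtures validate the
rules and the arithmetic, not the biology.

## Numerical and determinism choices

* Distance threshold comparisons are inclusive (≤) everywhere a boundary
  is stated (4.0 Å, 30 %, 75 %, 70/800 Da); the redundancy collapse is
  exclusive (> 90 %).
* All randomness flows through `numpy.random.default_rng(seed)`; the same
  seed gives byte-identical generated files and reports. Report floats are
  formatted to 6 significant digits; rows are deterministically ordered
  (combined score descending, ties by cluster id).
* Problem sizes in the test and acceptance runs (families of 6 members,
  complexes ≤ 200 atoms, distance matrices n ≤ 6, 50–200 replicates) were
  chosen as the smallest sizes at which every rule and tie-break is
  exercised; all scale linearly or quadratically if enlarged.

## Known limitations

* Insertion codes are parsed but alignment files address residues by
  integer author number only.
* The footprint rule, Eq-style summation span, overlap denominator and
  PSSM gap handling each had two defensible readings; the defaults chosen
  are documented above and every alternative is a config switch.
* No structure superposition, neighbor discovery, sequence search,
  assembly generation or affinity estimation: alignments are inputs.
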