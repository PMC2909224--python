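"""Query-anchored pairwise alignments and their composition.

Structure superpositions themselves are upstream inputs: each file gives a
residue-level alignment between the query chain and one structure neighbor,
with a per-position structural-equivalence flag.  Neighbors are admitted at
>=30 % sequence identity over the aligned (superimposed) positions.  To
compare two neighbors A and B, their alignments are composed *through the
query* (A->query followed by query->B), so that only regions relevant to
the query can carry binding-site information.  A neighbor site transfers to
the query only if at least 75 % of its contacts fall inside the alignment
footprint.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .errors import (CompositionError, CoordinateError,
                     MalformedAlignmentError, UndefinedIdentityError)
from .structure import BindingSite


@dataclass(frozen=True)
class AlignedPair:
    q_res: int            # author residue number on the query
    n_res: int            # author residue number on the neighbor
    q_aa: str
    n_aa: str
    equivalent: bool      # structurally equivalent position


@dataclass
class PairwiseAlignment:
    query_id: str
    neighbor_id: str
    pairs: list[AlignedPair]

    def __post_init__(self):
        self.pairs = sorted(self.pairs, key=lambda p: p.q_res)
        self._validate()

    def _validate(self):
        q_seen, n_seen = set(), set()
        prev_n = None
        for p in self.pairs:
            if p.q_res in q_seen or p.n_res in n_seen:
                raise MalformedAlignmentError(
                    f"{self.query_id}/{self.neighbor_id}: residue aligned twice "
                    f"(q{p.q_res}/n{p.n_res})")
            q_seen.add(p.q_res)
            n_seen.add(p.n_res)
            if prev_n is not None and p.n_res <= prev_n:
                raise MalformedAlignmentError(
                    f"{self.query_id}/{self.neighbor_id}: crossing pairs at "
                    f"q{p.q_res}/n{p.n_res}")
            prev_n = p.n_res

    @property
    def percent_identity(self) -> float:
        """Identity over aligned (superimposed) positions, as a fraction."""
        if not self.pairs:
            raise UndefinedIdentityError(
                f"{self.query_id}/{self.neighbor_id}: no aligned positions")
        matches = sum(1 for p in self.pairs if p.q_aa.upper() == p.n_aa.upper())
        return matches / len(self.pairs)

    def query_to_neighbor(self) -> dict[int, AlignedPair]:
        return {p.q_res: p for p in self.pairs}

    def neighbor_to_query(self) -> dict[int, AlignedPair]:
        return {p.n_res: p for p in self.pairs}


@dataclass(frozen=True)
class ComposedPair:
    a_res: int
    b_res: int
    a_aa: str
    b_aa: str
    equivalent: bool      # AND of the two legs' flags


@dataclass
class ComposedAlignment:
    neighbor_a_id: str
    neighbor_b_id: str
    route: str            # the shared query id
    pairs: list[ComposedPair]

    def a_to_b(self) -> dict[int, ComposedPair]:
        return {p.a_res: p for p in self.pairs}

    def b_to_a(self) -> dict[int, ComposedPair]:
        return {p.b_res: p for p in self.pairs}


@dataclass
class MappedSite:
    """A neighbor binding site carried into the query frame."""

    site: BindingSite
    neighbor_id: str
    query_positions: list[int]            # query numbering, aligned residues only
    neighbor_positions: list[int]         # matching neighbor residues
    fraction_in_footprint: float


def load_alignment(path, query_id: str | None = None,
                   neighbor_id: str | None = None,
                   chain_length: int | None = None) -> PairwiseAlignment:
    """Read one query-neighbor alignment.

    Two layouts are accepted:

    * TSV with a header line ``query_res neighbor_res q_aa n_aa equiv``
      (1-based author numbering, equiv 0/1); optional ``# query: ID`` and
      ``# neighbor: ID`` comment lines carry the identifiers;
    * pairwise FASTA with ``-`` gaps, two records (query first), plus an
      optional third record whose sequence is a 0/1 equivalence mask.

    Identifiers default to the filename stem split on ``__``.
    """
    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith(">"):
        return _load_fasta_alignment(text, path, query_id, neighbor_id)
    rows = []
    header = None
    for line in text.splitlines():
        if line.startswith("#"):
            key, _, val = line[1:].partition(":")
            key = key.strip().lower()
            if key == "query" and query_id is None:
                query_id = val.strip()
            elif key == "neighbor" and neighbor_id is None:
                neighbor_id = val.strip()
            continue
        if not line.strip():
            continue
        fields = line.split("\t")
        if header is None:
            header = [f.strip().lower() for f in fields]
            expected = ["query_res", "neighbor_res", "q_aa", "n_aa", "equiv"]
            if header != expected:
                raise MalformedAlignmentError(
                    f"{path}: header {header} != {expected}")
            continue
        q_res, n_res, q_aa, n_aa, equiv = fields
        rows.append(AlignedPair(int(q_res), int(n_res), q_aa.strip(),
                                n_aa.strip(), bool(int(equiv))))
    if query_id is None or neighbor_id is None:
        stem = path.name.split(".")[0]
        if "__" in stem:
            q, _, n = stem.partition("__")
            query_id = query_id or q
            neighbor_id = neighbor_id or n
        else:
            query_id = query_id or "query"
            neighbor_id = neighbor_id or stem
    if chain_length is not None:
        for p in rows:
            if not (1 <= p.q_res <= chain_length):
                raise CoordinateError(
                    f"{path}: query residue {p.q_res} outside chain "
                    f"of length {chain_length}")
    return PairwiseAlignment(query_id, neighbor_id, rows)


def _load_fasta_alignment(text, path, query_id, neighbor_id):
    records: list[tuple[str, str]] = []
    name, seq = None, []
    for line in text.splitlines():
        if line.startswith(">"):
            if name is not None:
                records.append((name, "".join(seq)))
            name, seq = line[1:].split()[0], []
        elif line.strip():
            seq.append(line.strip())
    if name is not None:
        records.append((name, "".join(seq)))
    if len(records) < 2:
        raise MalformedAlignmentError(f"{path}: need two aligned records")
    (qid, qseq), (nid, nseq) = records[0], records[1]
    mask = records[2][1] if len(records) > 2 else None
    if len(qseq) != len(nseq) or (mask and len(mask) != len(qseq)):
        raise MalformedAlignmentError(f"{path}: record lengths differ")
    pairs = []
    qi = ni = 0
    for k, (qa, na) in enumerate(zip(qseq, nseq)):
        if qa != "-":
            qi += 1
        if na != "-":
            ni += 1
        if qa != "-" and na != "-":
            equiv = mask[k] == "1" if mask else True
            pairs.append(AlignedPair(qi, ni, qa, na, equiv))
    return PairwiseAlignment(query_id or qid, neighbor_id or nid, pairs)


def write_alignment_tsv(aln: PairwiseAlignment, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# query: {aln.query_id}\n# neighbor: {aln.neighbor_id}\n")
        fh.write("query_res\tneighbor_res\tq_aa\tn_aa\tequiv\n")
        for p in aln.pairs:
            fh.write(f"{p.q_res}\t{p.n_res}\t{p.q_aa}\t{p.n_aa}\t{int(p.equivalent)}\n")


def identity_self_alignment(chain_id: str, sequence: str,
                            numbers: list[int] | None = None) -> PairwiseAlignment:
    """Identity alignment of a chain to itself (all positions equivalent).

    Used to place observed sites of the query structure into the common
    frame alongside inferred sites.
    """
    numbers = numbers or list(range(1, len(sequence) + 1))
    pairs = [AlignedPair(n, n, aa, aa, True) for n, aa in zip(numbers, sequence)]
    return PairwiseAlignment(chain_id, chain_id, pairs)


def admit_neighbor(aln: PairwiseAlignment, min_identity: float = 0.30) -> bool:
    """Homology gate: identity over superimposed positions >= threshold."""
    return aln.percent_identity >= min_identity


def compose_through_query(a: PairwiseAlignment,
                          b: PairwiseAlignment) -> ComposedAlignment:
    """Compose neighbor-A->query with query->neighbor-B.

    A pair (i, k) exists iff some query residue j is aligned to i in *a* and
    to k in *b*; its equivalence flag is the AND of the two legs.
    """
    if a.query_id != b.query_id:
        raise CompositionError(
            f"cannot compose: queries differ ({a.query_id} vs {b.query_id})")
    b_map = b.query_to_neighbor()
    pairs = []
    for pa in a.pairs:
        pb = b_map.get(pa.q_res)
        if pb is not None:
            pairs.append(ComposedPair(pa.n_res, pb.n_res, pa.n_aa, pb.n_aa,
                                      pa.equivalent and pb.equivalent))
    return ComposedAlignment(a.neighbor_id, b.neighbor_id, a.query_id, pairs)


def map_site_to_query(site: BindingSite, aln: PairwiseAlignment,
                      min_footprint: float = 0.75,
                      footprint_mode: str = "pairs") -> MappedSite | None:
    """Carry a neighbor site into query numbering, or reject it.

    ``footprint_mode='pairs'`` (default) weights the footprint fraction by
    atom-pair contacts; ``'residues'`` counts distinct residues.  The site
    is retained iff the fraction >= *min_footprint* (inclusive); rejection
    returns ``None``.
    """
    if footprint_mode not in ("pairs", "residues"):
        raise ValueError(f"unknown footprint_mode {footprint_mode!r}")
    n2q = aln.neighbor_to_query()
    covered_pairs = covered_res = 0
    total_pairs = total_res = 0
    q_positions, n_positions = [], []
    for num, _aa in site.residues:
        count = site.contact_counts[num]
        total_pairs += count
        total_res += 1
        pair = n2q.get(num)
        if pair is not None:
            covered_pairs += count
            covered_res += 1
            q_positions.append(pair.q_res)
            n_positions.append(num)
    if total_pairs == 0:
        return None
    if footprint_mode == "pairs":
        fraction = covered_pairs / total_pairs
    else:
        fraction = covered_res / total_res
    if fraction < min_footprint:
        return None
    order = sorted(range(len(q_positions)), key=lambda i: q_positions[i])
    return MappedSite(site, aln.neighbor_id,
                      [q_positions[i] for i in order],
                      [n_positions[i] for i in order],
                      fraction)
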