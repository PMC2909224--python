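"""Alignment loading, homology admission, composition and site mapping."""

import numpy as np
import pytest

from helpers import make_site
from homolig.align import (AlignedPair, PairwiseAlignment, admit_neighbor,
                           compose_through_query, load_alignment,
                           map_site_to_query, write_alignment_tsv)
from homolig.errors import (CompositionError, MalformedAlignmentError,
                            UndefinedIdentityError)


def aln(pairs, query="Q", neighbor="N"):
    return PairwiseAlignment(query, neighbor,
                             [AlignedPair(q, n, qa, na, eq)
                              for q, n, qa, na, eq in pairs])


def identity_aln(seq, query="Q", neighbor="N"):
    return aln([(i + 1, i + 1, a, a, True) for i, a in enumerate(seq)],
               query, neighbor)


def test_identity_alignment_has_full_identity():
    assert identity_aln("ACDEFGHIKL").percent_identity == 1.0


def test_one_mismatch_in_ten_gives_ninety_percent():
    pairs = [(i + 1, i + 1, "A", "A", True) for i in range(9)]
    pairs.append((10, 10, "A", "W", True))
    assert aln(pairs).percent_identity == pytest.approx(0.9)


def test_shuffled_rows_on_disk_canonicalize(tmp_path):
    a = identity_aln("ACDEF")
    path = tmp_path / "Q__N.aln.tsv"
    write_alignment_tsv(a, path)
    lines = path.read_text().splitlines()
    shuffled = lines[:3] + lines[3:][::-1]
    path.write_text("\n".join(shuffled) + "\n")
    b = load_alignment(path)
    assert [(p.q_res, p.n_res) for p in b.pairs] == \
        [(p.q_res, p.n_res) for p in a.pairs]
    assert (b.query_id, b.neighbor_id) == ("Q", "N")


def test_crossing_and_duplicate_pairs_rejected():
    with pytest.raises(MalformedAlignmentError):
        aln([(1, 2, "A", "A", True), (2, 1, "A", "A", True)])
    with pytest.raises(MalformedAlignmentError):
        aln([(1, 1, "A", "A", True), (1, 2, "A", "A", True)])


def test_empty_alignment_identity_is_undefined():
    empty = PairwiseAlignment("Q", "N", [])
    with pytest.raises(UndefinedIdentityError):
        _ = empty.percent_identity


def test_fasta_alignment_with_equivalence_mask(tmp_path):
    path = tmp_path / "pair.fasta"
    path.write_text(">Q\nAC-DE\n>N\nACWD-\n>mask\n11010\n")
    a = load_alignment(path)
    assert [(p.q_res, p.n_res, p.equivalent) for p in a.pairs] == \
        [(1, 1, True), (2, 2, True), (3, 4, True)]
    # the third aligned column (D/D) carries mask value 1; gapped columns skip
    assert a.percent_identity == pytest.approx(1.0)


@pytest.mark.parametrize("identity,expected", [
    (0.30, True),     # boundary inclusive: "at least 30%"
    (0.29, False),
    (1.00, True),
])
def test_neighbor_admission_threshold(identity, expected):
    n = 100
    k = int(round(identity * n))
    pairs = [(i + 1, i + 1, "A", "A" if i < k else "W", True)
             for i in range(n)]
    assert admit_neighbor(aln(pairs)) is expected


def test_composition_of_identities_is_identity():
    a = identity_aln("ACDEFGHIKL", neighbor="N1")
    b = identity_aln("ACDEFGHIKL", neighbor="N2")
    comp = compose_through_query(a, b)
    assert [(p.a_res, p.b_res) for p in comp.pairs] == \
        [(i + 1, i + 1) for i in range(10)]
    assert all(p.equivalent for p in comp.pairs)


def test_composition_covers_exactly_the_query_overlap():
    a = aln([(q, q, "A", "A", True) for q in range(1, 6)], neighbor="N1")
    b = aln([(q, q, "A", "A", True) for q in range(4, 9)], neighbor="N2")
    comp = compose_through_query(a, b)
    assert [(p.a_res, p.b_res) for p in comp.pairs] == [(4, 4), (5, 5)]
    empty = compose_through_query(a, PairwiseAlignment("Q", "N3", []))
    assert empty.pairs == []


def test_composition_requires_shared_query():
    a = identity_aln("ACD", query="Q1")
    b = identity_aln("ACD", query="Q2")
    with pytest.raises(CompositionError):
        compose_through_query(a, b)


def test_composition_matches_set_intersection_oracle():
    rng = np.random.default_rng(5)
    for _ in range(30):
        qlen = 30
        picks_a = sorted(rng.choice(qlen, size=12, replace=False) + 1)
        picks_b = sorted(rng.choice(qlen, size=12, replace=False) + 1)
        a = aln([(int(q), i + 1, "A", "C", bool(rng.integers(2)))
                 for i, q in enumerate(picks_a)], neighbor="N1")
        b = aln([(int(q), i + 1, "A", "D", bool(rng.integers(2)))
                 for i, q in enumerate(picks_b)], neighbor="N2")
        comp = compose_through_query(a, b)
        # oracle: intersect the query coverage sets directly
        qa = {p.q_res: p for p in a.pairs}
        qb = {p.q_res: p for p in b.pairs}
        expected = sorted((qa[q].n_res, qb[q].n_res)
                          for q in set(qa) & set(qb))
        assert sorted((p.a_res, p.b_res) for p in comp.pairs) == expected
        for p in comp.pairs:
            q = next(q for q in qa if qa[q].n_res == p.a_res)
            assert p.equivalent == (qa[q].equivalent and qb[q].equivalent)


def test_self_composition_is_identity_on_coverage():
    a = aln([(q, q + 3, "A", "A", True) for q in (1, 4, 7, 9)])
    comp = compose_through_query(a, a)
    assert all(p.a_res == p.b_res for p in comp.pairs)
    assert len(comp.pairs) == 4


def _site_with_contacts(counts):
    """BindingSite with residue numbers 1..n and the given contact counts."""
    rng = np.random.default_rng(0)
    site = make_site(rng, n_residues=len(counts))
    numbers = list(range(1, len(counts) + 1))
    site.residues = [(n, "A") for n in numbers]
    site.contact_counts = dict(zip(numbers, counts))
    return site


def test_fully_aligned_site_is_retained_with_footprint_one():
    site = _site_with_contacts([4, 4, 4, 4, 4])
    a = identity_aln("AAAAA")
    mapped = map_site_to_query(site, a)
    assert mapped is not None
    assert mapped.fraction_in_footprint == 1.0
    assert mapped.query_positions == [1, 2, 3, 4, 5]


@pytest.mark.parametrize("first_count,expected_kept", [
    (14, False),     # 14/20 = 0.70 < 0.75
    (15, True),      # 15/20 = 0.75, boundary inclusive
])
def test_footprint_rule_boundary(first_count, expected_kept):
    # 20 atom-pair contacts total; the alignment covers only residue 1
    rest = [2, 2, 20 - first_count - 4]
    site = _site_with_contacts([first_count] + rest)
    assert site.total_contacts == 20
    mapped = map_site_to_query(site, aln([(1, 1, "A", "A", True)]))
    assert (mapped is not None) is expected_kept


def test_footprint_modes_and_order_invariance():
    site = _site_with_contacts([10, 1, 1, 1, 1])
    a = aln([(1, 1, "A", "A", True)])       # only the 10-contact residue
    pairs_mode = map_site_to_query(site, a, min_footprint=0.5,
                                   footprint_mode="pairs")
    res_mode = map_site_to_query(site, a, min_footprint=0.5,
                                 footprint_mode="residues")
    assert pairs_mode is not None            # 10/14 pairs
    assert res_mode is None                  # 1/5 residues

    shuffled = _site_with_contacts([10, 1, 1, 1, 1])
    shuffled.residues = list(reversed(shuffled.residues))
    assert map_site_to_query(shuffled, a, 0.5).fraction_in_footprint == \
        pairs_mode.fraction_in_footprint
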