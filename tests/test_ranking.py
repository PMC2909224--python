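"""Cluster relevance terms, Z-score combination and ranking rules."""

import math

import numpy as np
import pytest

from homolig.matrix import load_matrix
from homolig.ranking import (PSSM_ALPHABET, ClusterScore, SiteAlignment,
                             avg_identity_to_query, avg_interfacial_contacts,
                             build_pssm, conservation_entropy,
                             henikoff_weights, is_singleton, pssm_score_query,
                             rank_clusters)

B62 = load_matrix()


class TestHenikoffWeights:
    def test_identical_sequences_share_weight_equally(self):
        for n in (1, 2, 5):
            w = henikoff_weights(["ACDE"] * n)
            np.testing.assert_allclose(w, np.full(n, 1 / n))

    def test_two_sequences_with_one_mismatch_stay_symmetric(self):
        w = henikoff_weights(["ACDE", "ACDF"])
        np.testing.assert_allclose(w, [0.5, 0.5])

    def test_hand_computed_three_sequence_example(self):
        # columns: AAA / CCC / DDG / EFG
        # col3: r=2, D members get 1/4 each, G gets 1/2
        # col4: r=3, each 1/3; cols 1-2: 1/3 each
        # raw: (1/3+1/3+1/4+1/3, same, 1/3+1/3+1/2+1/3) = (1.25, 1.25, 1.5)
        w = henikoff_weights(["ACDE", "ACDF", "ACGG"])
        np.testing.assert_allclose(w, [1.25 / 4, 1.25 / 4, 1.5 / 4])

    def test_divergent_member_gains_weight(self):
        w = henikoff_weights(["AAAA", "AAAA", "WYWY"])
        assert w[2] > w[0] == w[1]

    def test_zero_length_alignment_rejected(self):
        with pytest.raises(ValueError):
            henikoff_weights(["", ""])


class TestConservation:
    def test_fully_conserved_alignment_scores_one(self):
        aln = SiteAlignment([1, 2, 3], ["a", "b"], ["ACD", "ACD"])
        w = henikoff_weights(aln.rows)
        assert conservation_entropy(aln, w) == pytest.approx(1.0)

    def test_uniform_twenty_residue_column_contributes_zero(self):
        rows = [aa for aa in "ARNDCQEGHILKMFPSTWYV"]
        aln = SiteAlignment([1], [str(i) for i in range(20)], rows)
        w = np.full(20, 1 / 20)
        assert conservation_entropy(aln, w) == pytest.approx(0.0, abs=1e-12)

    def test_weighted_two_column_hand_example(self):
        aln = SiteAlignment([1, 2], ["a", "b"], ["AA", "AC"])
        w = np.array([0.5, 0.5])
        expected = (1.0 + (1.0 - math.log(2) / math.log(20))) / 2
        assert conservation_entropy(aln, w) == pytest.approx(expected)

    def test_gap_columns_are_renormalized(self):
        aln = SiteAlignment([1], ["a", "b"], ["A", "-"])
        w = np.array([0.5, 0.5])
        # only the non-gap member counts: fully conserved column
        assert conservation_entropy(aln, w) == pytest.approx(1.0)


class TestPssm:
    def test_single_sequence_column_reproduces_matrix_row(self):
        aln = SiteAlignment([1], ["a"], ["A"])
        pssm = build_pssm(aln, np.array([1.0]), B62)
        for i, aa in enumerate(PSSM_ALPHABET):
            assert pssm[0, i] == pytest.approx(float(B62["A", aa]))

    def test_half_half_column_is_the_mean_of_two_rows(self):
        aln = SiteAlignment([1], ["a", "b"], ["A", "G"])
        pssm = build_pssm(aln, np.array([0.5, 0.5]), B62)
        for i, aa in enumerate(PSSM_ALPHABET):
            expected = (float(B62["A", aa]) + float(B62["G", aa])) / 2
            assert pssm[0, i] == pytest.approx(expected)

    def test_query_identical_to_single_member_scores_blosum_diagonal(self):
        residues = "ACDEF"
        aln = SiteAlignment(list(range(1, 6)), ["a"], [residues])
        pssm = build_pssm(aln, np.array([1.0]), B62)
        expected = sum(float(B62[aa, aa]) for aa in residues)
        assert pssm_score_query(pssm, list(residues)) == pytest.approx(expected)

    def test_empty_overlap_scores_zero(self):
        pssm = np.zeros((0, 20))
        assert pssm_score_query(pssm, []) == 0.0

    def test_consensus_query_beats_scrambled_query(self):
        rng = np.random.default_rng(6)
        residues = list("ACDEFGHKLM")
        aln = SiteAlignment(list(range(1, 11)), ["a", "b"],
                            ["".join(residues)] * 2)
        w = np.array([0.5, 0.5])
        pssm = build_pssm(aln, w, B62)
        consensus = pssm_score_query(pssm, residues)
        for _ in range(5):
            scrambled = list(rng.permutation(residues))
            assert pssm_score_query(pssm, scrambled) <= consensus

    def test_gap_mode_column_min(self):
        aln = SiteAlignment([1], ["a"], ["A"])
        pssm = build_pssm(aln, np.array([1.0]), B62)
        assert pssm_score_query(pssm, ["-"]) == pytest.approx(pssm[0].min())
        assert pssm_score_query(pssm, ["-"], gap_mode="zero") == 0.0


def test_average_terms():
    assert avg_interfacial_contacts([10, 20]) == 15.0
    assert avg_interfacial_contacts([7]) == 7.0
    assert avg_identity_to_query([0.4, 0.6]) == pytest.approx(0.5)
    rng = np.random.default_rng(10)
    vals = rng.uniform(0, 50, size=9).tolist()
    assert avg_interfacial_contacts(vals) == pytest.approx(sum(vals) / 9)


class TestSingletonRule:
    def test_near_identical_members_collapse_to_singleton(self):
        base = "ACDEFGHIKLMNPQRSTVWY" * 2     # 40 residues
        variant = "C" + base[1:]              # 39/40 = 97.5 % identical
        assert is_singleton([base, base, variant, base, variant])

    def test_divergent_pair_is_not_singleton(self):
        a = "ACDEFGHIKL"
        b = "AWDYFGWKLV"                      # 50 % identical
        assert not is_singleton([a, b])

    def test_one_member_is_singleton(self):
        assert is_singleton(["ACDEF"])

    def test_boundary_is_exclusive(self):
        # exactly 90 % identity is NOT redundant ("more than 90%")
        a = "A" * 10
        b = "C" + "A" * 9                     # 90 %
        assert not is_singleton([a, b], redundancy_cutoff=0.90)


def make_scores(term_rows, **flags):
    out = []
    for i, (cons, pssm, cont, ident) in enumerate(term_rows):
        out.append(ClusterScore(
            cluster_id=f"C{i+1}", member_ids=[f"m{i}"], ligand_codes=["LIG"],
            query_positions=[1, 2, 3], conservation=cons, pssm_score=pssm,
            avg_contacts=cont, avg_identity=ident,
            singleton=flags.get("singleton", [False] * len(term_rows))[i],
            nonbiological=flags.get("nonbio", [False] * len(term_rows))[i]))
    return out


class TestRanking:
    def test_lone_cluster_gets_zero_z_and_rank_one(self):
        ann = rank_clusters(make_scores([(0.9, 30, 12, 0.5)]))
        assert ann.ranked[0].rank == 1
        assert ann.ranked[0].z == (0, 0, 0, 0)

    def test_one_two_three_gives_unit_sample_z(self):
        rows = [(1, 1, 1, 1), (2, 2, 2, 2), (3, 3, 3, 3)]
        ann = rank_clusters(make_scores(rows))
        by_id = {s.cluster_id: s for s in ann.ranked}
        np.testing.assert_allclose(by_id["C1"].z, [-1, -1, -1, -1])
        np.testing.assert_allclose(by_id["C2"].z, [0, 0, 0, 0])
        np.testing.assert_allclose(by_id["C3"].z, [1, 1, 1, 1])
        assert [s.cluster_id for s in ann.ranked] == ["C3", "C2", "C1"]

    def test_z_terms_have_zero_mean_unit_sample_sd(self):
        rng = np.random.default_rng(13)
        rows = [tuple(rng.uniform(0, 10, size=4)) for _ in range(7)]
        ann = rank_clusters(make_scores(rows))
        z = np.array([s.z for s in ann.ranked])
        np.testing.assert_allclose(z.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=0, ddof=1), 1, atol=1e-12)

    def test_dominant_cluster_ranks_first_for_any_positive_weights(self):
        rng = np.random.default_rng(14)
        for _ in range(20):
            rows = [tuple(rng.uniform(0, 5, size=4)) for _ in range(4)]
            dominant = tuple(max(r[j] for r in rows) + rng.uniform(0.1, 1)
                             for j in range(4))
            weights = tuple(rng.uniform(0.1, 3, size=4))
            ann = rank_clusters(make_scores([dominant] + rows), weights)
            assert ann.ranked[0].cluster_id == "C1"

    def test_ranking_invariant_under_positive_affine_term_transform(self):
        rng = np.random.default_rng(15)
        rows = [tuple(rng.uniform(0, 5, size=4)) for _ in range(5)]
        order1 = [s.cluster_id for s in rank_clusters(make_scores(rows)).ranked]
        # rescale the contact term: x -> 7x + 3 for every cluster
        rows2 = [(c, p, 7 * k + 3, i) for c, p, k, i in rows]
        order2 = [s.cluster_id for s in rank_clusters(make_scores(rows2)).ranked]
        assert order1 == order2

    def test_singletons_rank_after_all_scored_clusters(self):
        rows = [(3, 3, 3, 3), (1, 1, 1, 1), (2, 2, 2, 2)]
        ann = rank_clusters(make_scores(rows,
                                        singleton=[False, True, False]))
        assert [s.cluster_id for s in ann.ranked] == ["C1", "C3", "C2"]
        assert ann.ranked[-1].singleton
        assert ann.ranked[-1].combined is None

    def test_nonbiological_clusters_never_appear_in_the_ranked_list(self):
        rows = [(3, 3, 3, 3), (9, 9, 9, 9)]
        ann = rank_clusters(make_scores(rows, nonbio=[False, True]))
        assert [s.cluster_id for s in ann.ranked] == ["C1"]
        assert [s.cluster_id for s in ann.excluded] == ["C2"]
        assert ann.excluded[0].rank is None

    def test_all_singletons_is_a_valid_outcome(self):
        rows = [(1, 1, 1, 1), (2, 2, 2, 2)]
        ann = rank_clusters(make_scores(rows, singleton=[True, True]))
        assert all(s.singleton and s.combined is None for s in ann.ranked)
        assert [s.rank for s in ann.ranked] == [1, 2]
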