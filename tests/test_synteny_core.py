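import math

import numpy as np
import pytest

from synscale import simulate, synteny_core
from synscale.errors import DomainError, InsufficientOrthologsError
from synscale.synteny_core import (
    Arrangement,
    SyntenyConfig,
    arrangement_score,
    build_arrangements,
    canonicalize_orthologs,
    synteny_coverage,
    synteny_matrix,
    synteny_similarity,
)
from synscale.types import GeneOrder, OrthologSet

from conftest import random_synteny_case
from oracles import brute_force_synteny


def full_orthology(order_a, order_b, mapping):
    return OrthologSet(order_a.genome_id, order_b.genome_id, mapping)


class TestArrangements:
    def test_pivot_rotation_by_hand(self):
        a = GeneOrder("A", ("g1", "g2", "g3"))
        b = GeneOrder("B", ("h1", "h2", "h3"))
        orth = full_orthology(a, b, [("g1", "h1"), ("g2", "h2")])
        arrs = build_arrangements(a, b, orth)
        pivot_g2 = arrs[2]  # pivot on second ortholog pair
        assert pivot_g2.rank_a == {"g2": 1, "g3": 2, "g1": 3}
        assert pivot_g2.rank_b == {"h2": 1, "h3": 2, "h1": 3}

    def test_pivot_on_first_gene_equals_original(self):
        a = GeneOrder("A", ("g1", "g2", "g3"))
        b = GeneOrder("B", ("h1", "h2", "h3"))
        orth = full_orthology(a, b, [("g1", "h1"), ("g3", "h3")])
        arrs = build_arrangements(a, b, orth)
        assert arrs[1].rank_a == arrs[0].rank_a
        assert arrs[1].rank_b == arrs[0].rank_b

    def test_arrangement_count_is_pairs_plus_one(self):
        a = GeneOrder("A", ("g1", "g2", "g3"))
        b = GeneOrder("B", ("h1", "h2", "h3"))
        orth = full_orthology(a, b, [("g1", "h1"), ("g2", "h2"), ("g3", "h3")])
        assert len(build_arrangements(a, b, orth)) == 4

    def test_fewer_than_two_pairs_is_skip_signal(self):
        a = GeneOrder("A", ("g1", "g2"))
        b = GeneOrder("B", ("h1", "h2"))
        with pytest.raises(InsufficientOrthologsError):
            build_arrangements(a, b, OrthologSet("A", "B", [("g1", "h1")]))

    def test_ranks_are_permutations(self, rng):
        for _ in range(20):
            a, b, orth = random_synteny_case(rng)
            for arr in build_arrangements(a, b, orth):
                assert sorted(arr.rank_a.values()) == list(range(1, len(a) + 1))
                assert sorted(arr.rank_b.values()) == list(range(1, len(b) + 1))


class TestArrangementScore:
    def test_identical_ranks_score_one(self):
        arr = Arrangement("original", {"g1": 1, "g2": 2}, {"h1": 1, "h2": 2})
        orth = OrthologSet("A", "B", [("g1", "h1"), ("g2", "h2")])
        assert arrangement_score(arr, orth) == pytest.approx(1.0, abs=1e-15)

    def test_single_combination_reversal_cosine(self):
        # u = (1, 2), v = (2, 1): cosine = 4/5
        arr = Arrangement("original", {"g1": 1, "g2": 2}, {"h1": 2, "h2": 1})
        orth = OrthologSet("A", "B", [("g1", "h1"), ("g2", "h2")])
        assert arrangement_score(arr, orth) == pytest.approx(0.8, abs=1e-15)

    def test_three_pair_reversal_mean(self):
        arr = Arrangement(
            "original",
            {"g1": 1, "g2": 2, "g3": 3},
            {"h1": 3, "h2": 2, "h3": 1},
        )
        orth = OrthologSet(
            "A", "B", [("g1", "h1"), ("g2", "h2"), ("g3", "h3")]
        )
        expected = (2 * 7 / math.sqrt(65) + 0.6) / 3
        assert arrangement_score(arr, orth) == pytest.approx(expected, abs=1e-14)

    def test_scale_invariance_of_genome_vectors(self):
        # multiplying one genome's ranks by a constant scales u uniformly
        base = Arrangement(
            "original", {"g1": 1, "g2": 2, "g3": 3}, {"h1": 2, "h2": 3, "h3": 1}
        )
        scaled = Arrangement(
            "original",
            {k: 7 * v for k, v in base.rank_a.items()},
            dict(base.rank_b),
        )
        orth = OrthologSet("A", "B", [("g1", "h1"), ("g2", "h2"), ("g3", "h3")])
        assert arrangement_score(base, orth) == pytest.approx(
            arrangement_score(scaled, orth), abs=1e-14
        )


class TestSyntenySimilarity:
    def test_exact_copy_scores_one(self):
        a = GeneOrder("A", ("g1", "g2", "g3", "g4"))
        b = GeneOrder("B", ("h1", "h2", "h3", "h4"))
        orth = full_orthology(a, b, [(f"g{i}", f"h{i}") for i in range(1, 5)])
        res = synteny_similarity(a, b, orth)
        assert res.similarity == pytest.approx(1.0, abs=1e-15)

    def test_two_gene_reversal_scores(self):
        we = simulate.worked_example()
        res = synteny_similarity(*we.two_gene)
        assert sorted(res.per_arrangement_scores) == pytest.approx(
            [0.8, 1.0, 1.0], abs=1e-15
        )
        assert res.similarity == pytest.approx(1.0, abs=1e-15)

    def test_three_gene_full_reversal_scores(self):
        we = simulate.worked_example()
        res = synteny_similarity(*we.three_gene)
        assert res.per_arrangement_scores == pytest.approx(
            list(we.expected_three_gene_scores), abs=1e-14
        )
        assert res.similarity == pytest.approx(
            we.expected_three_gene_median, abs=1e-14
        )

    def test_symmetry_under_genome_swap(self, rng):
        for _ in range(25):
            a, b, orth = random_synteny_case(rng)
            fwd = synteny_similarity(a, b, orth).similarity
            rev = synteny_similarity(b, a, orth.swapped()).similarity
            assert fwd == pytest.approx(rev, abs=1e-12)

    def test_similarity_in_half_open_unit_interval(self, rng):
        for _ in range(25):
            a, b, orth = random_synteny_case(rng)
            res = synteny_similarity(a, b, orth)
            assert 0.0 < res.similarity <= 1.0
            assert all(0.0 < s <= 1.0 for s in res.per_arrangement_scores)

    def test_rotation_invariance(self, rng):
        # any circular rotation of a genome with full orthology scores 1
        for offset in (1, 3, 6):
            genes = tuple(f"g{i}" for i in range(8))
            rotated = genes[offset:] + genes[:offset]
            a = GeneOrder("A", genes)
            b = GeneOrder("B", tuple(g.replace("g", "h") for g in rotated))
            orth = OrthologSet("A", "B", [(g, g.replace("g", "h")) for g in genes])
            res = synteny_similarity(a, b, orth)
            assert res.similarity == pytest.approx(1.0, abs=1e-12)

    def test_oracle_equivalence_small_genomes(self, rng):
        for _ in range(100):
            a, b, orth = random_synteny_case(rng, max_genes=6)
            res = synteny_similarity(a, b, orth)
            expected, scores = brute_force_synteny(
                list(a.ordered_gene_ids), list(b.ordered_gene_ids), orth.pairs
            )
            assert res.similarity == pytest.approx(expected, abs=1e-12)
            assert res.per_arrangement_scores == pytest.approx(scores, abs=1e-12)

    def test_oracle_equivalence_other_configs(self, rng):
        for mode in ("genome-vectors", "ortholog-vectors"):
            for within in ("mean", "median"):
                cfg = SyntenyConfig(vector_mode=mode, within_arrangement=within)
                for _ in range(15):
                    a, b, orth = random_synteny_case(rng, max_genes=5)
                    res = synteny_similarity(a, b, orth, cfg)
                    expected, _ = brute_force_synteny(
                        list(a.ordered_gene_ids),
                        list(b.ordered_gene_ids),
                        orth.pairs,
                        vector_mode=mode,
                        within=within,
                    )
                    assert res.similarity == pytest.approx(expected, abs=1e-12)


class TestCanonicalization:
    def test_best_identity_wins(self):
        orth = OrthologSet(
            "A", "B",
            [("a1", "b1"), ("a1", "b2"), ("a2", "b2")],
            identity_pct=[98.0, 99.5, 97.0],
            aligned_length_bp=[900, 900, 800],
        )
        canon = canonicalize_orthologs(orth)
        assert canon.pairs == [("a1", "b2")] or ("a1", "b2") in canon.pairs
        assert canon.is_one_to_one()

    def test_one_to_one_after_canonicalization(self, rng):
        genes_a = [f"a{i}" for i in range(6)]
        genes_b = [f"b{i}" for i in range(6)]
        pairs = [(a, b) for a in genes_a for b in genes_b]
        idents = list(rng.uniform(90, 100, size=len(pairs)))
        orth = OrthologSet("A", "B", pairs, idents, [500] * len(pairs))
        canon = canonicalize_orthologs(orth)
        assert canon.is_one_to_one()
        assert len(canon.pairs) == 6


class TestSyntenyMatrix:
    def test_missing_pairs_are_zero_with_unit_diagonal(self):
        orders = {
            "A": GeneOrder("A", ("a1", "a2", "a3")),
            "B": GeneOrder("B", ("b1", "b2", "b3")),
            "C": GeneOrder("C", ("c1", "c2", "c3")),
        }
        osets = [OrthologSet("A", "B", [("a1", "b1"), ("a2", "b2")])]
        m = synteny_matrix(orders, osets)
        assert m.zero_is_missing
        np.testing.assert_array_equal(np.diag(m.values), 1.0)
        assert m.values[0, 2] == 0.0 and m.values[1, 2] == 0.0
        assert m.values[0, 1] > 0.0

    def test_matrix_is_exactly_symmetric(self, rng):
        cfg = simulate.SimulationConfig(n_genomes=6, n_groups=2, seed=11)
        corpus = simulate.simulate_corpus(cfg)
        m = synteny_matrix(corpus.orders, corpus.ortholog_sets)
        np.testing.assert_array_equal(m.values, m.values.T)

    def test_genome_vs_rotated_copy_scores_one(self):
        genes = tuple(f"g{i}" for i in range(10))
        orders = {
            "A": GeneOrder("A", genes),
            "B": GeneOrder("B", tuple("r" + g for g in genes[4:] + genes[:4])),
        }
        osets = [OrthologSet("A", "B", [(g, "r" + g) for g in genes])]
        m = synteny_matrix(orders, osets)
        assert m.values[0, 1] == pytest.approx(1.0, abs=1e-12)


class TestCoverage:
    def test_hand_arithmetic(self):
        order = GeneOrder("A", ("g1", "g2"), genome_length_bp=1000)
        orth = OrthologSet("A", "B", [("g1", "h1"), ("g2", "h2")],
                           aligned_length_bp=[200, 300])
        assert synteny_coverage(order, orth, "a") == pytest.approx(0.5)

    def test_no_shared_blocks_is_zero(self):
        order = GeneOrder("A", ("g1",), genome_length_bp=1000)
        orth = OrthologSet("A", "B", [], aligned_length_bp=[])
        assert synteny_coverage(order, orth, "a") == 0.0

    def test_fully_tiled_genome_is_one(self):
        order = GeneOrder("A", ("g1", "g2"), genome_length_bp=1000)
        orth = OrthologSet("A", "B", [("g1", "h1"), ("g2", "h2")],
                           aligned_length_bp=[600, 400])
        assert synteny_coverage(order, orth, "a") == pytest.approx(1.0)

    def test_overlapping_blocks_use_union_length(self):
        order = GeneOrder("A", ("g1", "g2"), genome_length_bp=1000)
        orth = OrthologSet("A", "B", [("g1", "h1"), ("g2", "h2")])
        intervals = {"g1": (1, 600), "g2": (401, 800)}
        assert synteny_coverage(order, orth, "a", intervals) == pytest.approx(0.8)

    def test_asymmetric_between_genomes(self):
        order_a = GeneOrder("A", ("g1",), genome_length_bp=2000)
        order_b = GeneOrder("B", ("h1",), genome_length_bp=500)
        orth = OrthologSet("A", "B", [("g1", "h1")], aligned_length_bp=[400])
        ca = synteny_coverage(order_a, orth, "a")
        cb = synteny_coverage(order_b, orth, "b")
        assert ca == pytest.approx(0.2)
        assert cb == pytest.approx(0.8)

    def test_zero_length_genome_rejected(self):
        with pytest.raises(DomainError):
            GeneOrder("A", ("g1",), genome_length_bp=0)
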