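"""Shared-neighbor statistic and the DCPred ranking models."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from cocktailnet.dcpred import (
    candidate_pairs,
    rank_candidates,
    shared_neighbor_pvalue,
)

from .conftest import make_drug


def _sigfig(x, n):
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (n - 1))


class TestPointProbability:
    @pytest.mark.parametrize(
        "m, n1, n2, expected, sig",
        [
            (2, 2, 2, 4.35e-05, 3),
            (2, 2, 3, 0.000130406, 6),
            (2, 2, 4, 0.000260813, 6),
        ],
    )
    def test_worked_values_at_n215(self, m, n1, n2, expected, sig):
        """Shared-neighbor probabilities for low-degree pairs in a 215-drug network."""
        p = shared_neighbor_pvalue(m, n1, n2, 215)
        assert _sigfig(p, sig) == expected

    def test_empty_neighborhoods_give_certainty(self):
        assert shared_neighbor_pvalue(0, 0, 0, 10) == 1.0

    @pytest.mark.parametrize("n1, n2, N", [(5, 7, 30), (3, 3, 8), (10, 12, 25)])
    def test_distribution_normalizes(self, n1, n2, N):
        total = sum(
            shared_neighbor_pvalue(m, n1, n2, N) for m in range(min(n1, n2) + 1)
        )
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_equals_hypergeometric_point_probability(self):
        """Exhaustive agreement with scipy's hypergeometric pmf, N <= 20."""
        for N in range(1, 21):
            for n1 in range(N + 1):
                for n2 in range(N + 1):
                    for m in range(min(n1, n2) + 1):
                        ours = shared_neighbor_pvalue(m, n1, n2, N)
                        ref = stats.hypergeom.pmf(m, N, n1, n2)
                        assert ours == pytest.approx(ref, abs=1e-12), (m, n1, n2, N)

    def test_matches_random_subset_oracle(self):
        """Frequency of exact-m overlaps between random subsets."""
        m, n1, n2, N = 2, 4, 5, 15
        rng = np.random.default_rng(8)
        draws = 200_000
        hits = 0
        for _ in range(draws):
            a = set(rng.choice(N, size=n1, replace=False))
            b = set(rng.choice(N, size=n2, replace=False))
            hits += len(a & b) == m
        p_hat = hits / draws
        p = shared_neighbor_pvalue(m, n1, n2, N)
        se = math.sqrt(p * (1 - p) / draws)
        assert abs(p_hat - p) < 3 * se

    def test_symmetric_in_neighbor_counts(self):
        for N in (10, 50, 215):
            for n1, n2 in [(2, 7), (3, 9), (5, 5)]:
                for m in range(min(n1, n2) + 1):
                    assert shared_neighbor_pvalue(m, n1, n2, N) == pytest.approx(
                        shared_neighbor_pvalue(m, n2, n1, N), abs=0
                    )

    def test_strictly_decreasing_in_shared_count(self):
        """More shared partners -> smaller probability -> higher ranking."""
        for n1, n2, N in [(5, 7, 30), (4, 4, 215), (10, 15, 100)]:
            vals = [
                shared_neighbor_pvalue(m, n1, n2, N)
                for m in range(1, min(n1, n2) + 1)
            ]
            assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_tail_probability_accumulates_points(self):
        tail = shared_neighbor_pvalue(2, 5, 7, 30, tail=True)
        points = sum(shared_neighbor_pvalue(m, 5, 7, 30) for m in range(2, 6))
        assert tail == pytest.approx(points, abs=1e-12)
        assert shared_neighbor_pvalue(0, 5, 7, 30, tail=True) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "args, msg",
        [
            ((3, 2, 5, 10), "m"),
            ((1, 11, 5, 10), "N"),
            ((-1, 2, 2, 10), "m"),
        ],
    )
    def test_bound_violations_name_offender(self, args, msg):
        with pytest.raises(ValueError, match=msg):
            shared_neighbor_pvalue(*args)

    def test_non_integer_arguments_rejected(self):
        with pytest.raises(TypeError):
            shared_neighbor_pvalue(1.0, 2, 2, 10)


class TestCandidatePairs:
    def test_similar_triangle_all_pairs_eligible(self):
        drugs = {i: make_drug(i, ["C03AA01"]) for i in "abc"}
        net = nx.Graph([("a", "b"), ("b", "c"), ("a", "c")])
        assert len(candidate_pairs(net, drugs, "DCPred2")) == 3

    def test_dissimilar_drug_excluded(self):
        drugs = {
            "a": make_drug("a", ["C03AA01"]),
            "b": make_drug("b", ["C03AB02"]),
            "x": make_drug("x", ["N02BA01"]),
        }
        net = nx.Graph([("a", "b"), ("b", "x"), ("a", "x")])
        pairs = candidate_pairs(net, drugs, "DCPred1")
        assert pairs == [("a", "b")]

    def test_degree_filter_matches_brute_force(self, toy_dataset):
        drugs, _, net = toy_dataset
        from cocktailnet.atc import therapeutic_similarity

        for model, min_deg in [("DCPred1", 0), ("DCPred2", 2), ("DCPred3", 3)]:
            expected = {
                tuple(sorted((u, v)))
                for u, v in itertools.combinations(net.nodes(), 2)
                if net.degree(u) >= min_deg
                and net.degree(v) >= min_deg
                and therapeutic_similarity(drugs[u], drugs[v]) > 0
            }
            assert set(candidate_pairs(net, drugs, model)) == expected

    def test_unknown_model_rejected(self, toy_dataset):
        drugs, _, net = toy_dataset
        with pytest.raises(ValueError, match="unknown model"):
            candidate_pairs(net, drugs, "DCPred9")


def _ranking_oracle(pairs, net, drugs, model):
    """Independent re-scoring with scipy and a plain sort."""
    from cocktailnet.atc import therapeutic_similarity

    N = net.number_of_nodes()
    rows = []
    for a, b in pairs:
        a, b = sorted((a, b))
        m = len(set(net.neighbors(a)) & set(net.neighbors(b)))
        n1, n2 = net.degree(a), net.degree(b)
        p = float(stats.hypergeom.pmf(m, N, n1, n2))
        ts = therapeutic_similarity(drugs[a], drugs[b])
        rows.append((a, b, ts, p))
    if model == "DCPred1":
        rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    else:
        rows.sort(key=lambda r: (r[3], -r[2], r[0], r[1]))
    return [(a, b) for a, b, _, _ in rows]


class TestRanking:
    def test_more_shared_neighbors_ranks_higher(self):
        drugs = {i: make_drug(i, ["C03AA01"]) for i in "abcdwxyz"}
        # a,b share two neighbors; x,y share none; all degrees equal 2
        net = nx.Graph(
            [("a", "c"), ("b", "c"), ("a", "d"), ("b", "d"),
             ("x", "w"), ("y", "z"), ("x", "z"), ("y", "w")]
        )
        ranking = rank_candidates([("a", "b"), ("x", "y")], net, drugs, "DCPred2")
        assert (ranking[0].drug_a, ranking[0].drug_b) == ("a", "b")

    def test_ts_model_puts_identical_pair_first(self):
        drugs = {
            "a": make_drug("a", ["C03AA01"]),
            "b": make_drug("b", ["C03AA01"]),
            "c": make_drug("c", ["C09XX01"]),
        }
        net = nx.Graph([("a", "b"), ("b", "c"), ("a", "c")])
        ranking = rank_candidates(
            [("a", "b"), ("a", "c"), ("b", "c")], net, drugs, "DCPred1"
        )
        assert ranking[0].ts == 1.0 and {ranking[0].drug_a, ranking[0].drug_b} == {"a", "b"}

    @pytest.mark.parametrize("model", ["DCPred1", "DCPred2"])
    def test_full_ranking_matches_oracle_on_twelve_drug_fixture(self, model):
        rng = np.random.default_rng(21)
        ids = [f"d{i:02d}" for i in range(12)]
        codes = ["C03AA01", "C03AB02", "C09XX01", "N02BA01"]
        drugs = {d: make_drug(d, [codes[i % 4]]) for i, d in enumerate(ids)}
        net = nx.Graph()
        net.add_nodes_from(ids)
        for a, b in itertools.combinations(ids, 2):
            if rng.random() < 0.3:
                net.add_edge(a, b)
        pairs = candidate_pairs(net, drugs, model)
        ranking = rank_candidates(pairs, net, drugs, model)
        assert [(r.drug_a, r.drug_b) for r in ranking] == _ranking_oracle(
            pairs, net, drugs, model
        )
        assert [r.rank for r in ranking] == list(range(1, len(pairs) + 1))

    def test_ranking_invariant_to_input_order(self, toy_dataset):
        drugs, _, net = toy_dataset
        pairs = candidate_pairs(net, drugs, "DCPred2")
        fwd = rank_candidates(pairs, net, drugs, "DCPred2")
        rev = rank_candidates(list(reversed(pairs)), net, drugs, "DCPred2")
        assert fwd == rev

    def test_known_positive_marks_edges(self, toy_dataset):
        drugs, _, net = toy_dataset
        ranking = rank_candidates(
            candidate_pairs(net, drugs, "DCPred1"), net, drugs, "DCPred1"
        )
        for r in ranking:
            assert r.known_positive == net.has_edge(r.drug_a, r.drug_b)

    def test_exclude_pair_edge_reduces_degrees(self):
        drugs = {i: make_drug(i, ["C03AA01"]) for i in "abc"}
        net = nx.Graph([("a", "b"), ("b", "c"), ("a", "c")])
        base = rank_candidates([("a", "b")], net, drugs, "DCPred2")[0]
        excl = rank_candidates(
            [("a", "b")], net, drugs, "DCPred2", exclude_pair_edge=True
        )[0]
        assert (base.stat.n1, base.stat.n2) == (2, 2)
        assert (excl.stat.n1, excl.stat.n2) == (1, 1)
        assert base.stat.m == excl.stat.m == 1

    def test_empty_candidates_rejected(self, toy_dataset):
        drugs, _, net = toy_dataset
        with pytest.raises(ValueError):
            rank_candidates([], net, drugs, "DCPred2")
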