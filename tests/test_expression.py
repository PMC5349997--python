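"""RPKM, exact two-library count test, BY-FDR, DEG calling and clustering."""

import math

import numpy as np
import pandas as pd
import pytest

from epipair import (
    ExpressionMatrix,
    aggregate_across_pairs,
    by_fdr,
    call_pairwise_degs,
    cluster_degs,
    intersect_gene_list,
    pairwise_count_test,
    rpkm,
)
from epipair.expression import PairwiseDEGResult


class TestRPKM:
    def test_direct_formula(self):
        assert rpkm(1000, 2000, 10**7) == pytest.approx(50.0)

    def test_zero_count(self):
        assert rpkm(0, 2000, 10**7) == 0.0

    def test_joint_rescaling_invariance(self):
        assert rpkm(500, 1500, 10**6) == pytest.approx(
            rpkm(1000, 1500, 2 * 10**6)
        )

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError):
            rpkm(10, 1000, 0)


def _ac_tail_oracle(x, y, N1, N2):
    """Direct tail summation of the conditional distribution.

    p(j | x) = r^j (x+j)! / (x! j! (1+r)^(x+j+1)), r = N2/N1; summed until
    the terms vanish.
    """
    r = N2 / N1

    def pmf(j):
        return math.exp(
            j * math.log(r)
            + math.lgamma(x + j + 1)
            - math.lgamma(x + 1)
            - math.lgamma(j + 1)
            - (x + j + 1) * math.log1p(r)
        )

    lower = sum(pmf(j) for j in range(y + 1))
    upper = pmf(y)
    j = y + 1
    while True:
        term = pmf(j)
        upper += term
        if term < 1e-18 and j > 2 * (x + y + 10):
            break
        j += 1
    return min(1.0, 2.0 * min(lower, upper))


class TestPairwiseCountTest:
    def test_symmetric_point_is_insignificant(self):
        assert pairwise_count_test(50, 50, 10**6, 10**6) == 1.0

    def test_zero_zero(self):
        assert pairwise_count_test(0, 0, 10**6, 10**6) == 1.0

    @pytest.mark.parametrize("x, y", [(5, 25), (25, 5), (0, 12), (200, 140)])
    def test_matches_tail_sum_oracle_equal_libs(self, x, y):
        got = pairwise_count_test(x, y, 10**6, 10**6)
        assert got == pytest.approx(_ac_tail_oracle(x, y, 10**6, 10**6),
                                    rel=1e-9)

    def test_matches_oracle_unequal_libs(self):
        got = pairwise_count_test(30, 90, 10**6, 2 * 10**6)
        assert got == pytest.approx(
            _ac_tail_oracle(30, 90, 10**6, 2 * 10**6), rel=1e-9
        )

    def test_library_ratio_shifts_null(self):
        # 10 vs 20 is exactly proportional to libraries 1:2 -> not significant
        p = pairwise_count_test(100, 200, 10**6, 2 * 10**6)
        assert p > 0.5

    def test_large_counts_stable(self):
        p = pairwise_count_test(50_000, 50_500, 10**7, 10**7)
        assert 0.0 <= p <= 1.0 and np.isfinite(p)


class TestByFDR:
    def test_single_p_unchanged(self):
        assert by_fdr([0.005])[0] == pytest.approx(0.005)

    def test_three_values_harmonic_factor(self):
        # m*c(m) = 3 * (1 + 1/2 + 1/3) = 5.5; all step up to 0.055
        adj = by_fdr([0.01, 0.02, 0.03])
        assert np.allclose(adj, [0.055, 0.055, 0.055])

    def test_matches_step_up_oracle(self, rng):
        for _ in range(20):
            m = int(rng.integers(1, 40))
            p = rng.random(m)
            adj = by_fdr(p)
            # direct evaluation of the BY step-up formula
            c = np.sum(1.0 / np.arange(1, m + 1))
            order = np.argsort(p, kind="stable")
            sorted_adj = np.minimum(1.0, m * c * p[order]
                                    / np.arange(1, m + 1))
            sorted_adj = np.minimum.accumulate(sorted_adj[::-1])[::-1]
            expected = np.empty(m)
            expected[order] = sorted_adj
            assert np.allclose(adj, expected, atol=1e-12)

    def test_dominates_bh(self, rng):
        from scipy.stats import false_discovery_control

        p = rng.random(100)
        assert np.all(by_fdr(p) >= false_discovery_control(p, method="bh") - 1e-15)

    def test_monotone_in_raw_p(self, rng):
        p = rng.random(50)
        adj = by_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)


def _matrix(counts, lengths=None, samples=("s1", "s2")):
    counts = np.asarray(counts)
    genes = [f"g{i}" for i in range(counts.shape[0])]
    if lengths is None:
        lengths = np.full(counts.shape[0], 1000)
    return ExpressionMatrix.from_counts(
        pd.DataFrame(counts, index=genes, columns=list(samples)),
        pd.Series(lengths, index=genes),
    )


class TestCallPairwiseDEGs:
    def test_identical_counts_no_call(self):
        m = _matrix([[100, 100], [50, 50]])
        results = call_pairwise_degs(m, [("p1", "s1", "s2")])
        assert all(r.call == "none" for r in results)

    def test_planted_eightfold_gene_recovered(self, rng):
        n = 2000
        base = rng.poisson(200, size=(n, 2))
        base[0, 0] = rng.poisson(200 * 8)
        m = _matrix(base)
        results = call_pairwise_degs(m, [("p1", "s1", "s2")])
        by_gene = {r.gene_id: r for r in results}
        assert by_gene["g0"].call == "up"
        n_fp = sum(r.call != "none" for r in results) - 1
        assert n_fp <= 3

    def test_antisymmetric_under_swap(self, rng):
        counts = rng.poisson([[200, 40], [30, 300], [100, 100]])
        m = _matrix(counts)
        fwd = call_pairwise_degs(m, [("p1", "s1", "s2")])
        rev = call_pairwise_degs(m, [("p1", "s2", "s1")])
        flip = {"up": "down", "down": "up", "none": "none"}
        for f, r in zip(fwd, rev):
            assert r.call == flip[f.call]

    def test_zero_both_sides_excluded_from_family(self):
        m = _matrix([[0, 0], [500, 100], [80, 90]])
        results = call_pairwise_degs(m, [("p1", "s1", "s2")])
        assert results[0].call == "none" and results[0].p_value == 1.0


def _result(gene, pair, call):
    return PairwiseDEGResult(gene, pair, 0, 0, 1.0, 1.0, 0.0, 0.5, 0.5, call)


class TestAggregation:
    def test_counting_rule(self):
        pairs = [f"p{i}" for i in range(10)]
        results = [_result("gA", p, "up") for p in pairs[:6]]
        results += [_result("gA", pairs[6], "down")]
        results += [_result("gB", p, "up") for p in pairs[:2]]
        agg = aggregate_across_pairs(results, pairs, k_min=5)
        assert len(agg) == 1
        a = agg[0]
        assert (a.gene_id, a.n_pairs_called, a.n_up, a.n_down) == ("gA", 7, 6, 1)
        assert a.calls == (1, 1, 1, 1, 1, 1, -1, 0, 0, 0)

    def test_uncalled_gene_excluded(self):
        agg = aggregate_across_pairs([_result("g", "p0", "none")], ["p0"],
                                     k_min=1)
        assert agg == []

    def test_matches_recount(self, rng):
        pairs = [f"p{i}" for i in range(10)]
        results = []
        table = {}
        for g in range(30):
            for p in pairs:
                call = ("up", "down", "none")[int(rng.integers(3))]
                results.append(_result(f"g{g}", p, call))
                table[(f"g{g}", p)] = call
        agg = aggregate_across_pairs(results, pairs, k_min=3)
        for a in agg:
            n_called = sum(table[(a.gene_id, p)] != "none" for p in pairs)
            assert a.n_pairs_called == n_called >= 3


class TestIntersectGeneList:
    def test_empty_reference(self):
        agg = [
            __import__("epipair").AggregatedDEG("gA", 5, 5, 0, (1,) * 5)
        ]
        df = intersect_gene_list(agg, [])
        assert not df["in_reference"].any()

    def test_exact_case_sensitive_match(self):
        from epipair import AggregatedDEG

        agg = [AggregatedDEG("GeneA", 5, 5, 0, (1,) * 5),
               AggregatedDEG("geneB", 5, 0, 5, (-1,) * 5)]
        df = intersect_gene_list(agg, ["GeneA", "GENEB"])
        assert df.set_index("gene_id")["in_reference"].to_dict() == {
            "GeneA": True, "geneB": False
        }


def _average_linkage_oracle(X):
    """Quadratic brute-force agglomerative average linkage (UPGMA merges)."""
    clusters = {i: [i] for i in range(len(X))}
    heights = []
    next_id = len(X)
    dist = {
        (i, j): float(np.linalg.norm(X[i] - X[j]))
        for i in range(len(X))
        for j in range(i + 1, len(X))
    }

    def cdist(a, b):
        return float(np.mean([
            np.linalg.norm(X[p] - X[q]) for p in clusters[a] for q in clusters[b]
        ]))

    while len(clusters) > 1:
        keys = sorted(clusters)
        best = min(
            ((cdist(a, b), a, b) for i, a in enumerate(keys)
             for b in keys[i + 1:]),
            key=lambda t: (t[0], t[1], t[2]),
        )
        d, a, b = best
        heights.append(d)
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return heights


class TestClusterDEGs:
    def test_identical_rows_merge_at_zero(self):
        df = pd.DataFrame([[1, 0, -1], [1, 0, -1], [0, 1, 1]],
                          index=["a", "b", "c"])
        res = cluster_degs(df)
        assert res.linkage[0, 2] == 0.0
        assert set(res.leaf_order) == {"a", "b", "c"}

    def test_opposite_rows_maximally_distant(self):
        df = pd.DataFrame([[1] * 4, [-1] * 4, [1, 1, -1, -1]],
                          index=["up", "down", "mix"])
        res = cluster_degs(df)
        assert res.linkage[-1, 2] == pytest.approx(
            max(res.linkage[:, 2])
        )

    def test_merge_heights_match_brute_force(self, rng):
        # continuous rows: distance ties would make merge order
        # implementation-defined and the comparison ill-posed
        X = rng.standard_normal((20, 8))
        df = pd.DataFrame(X, index=[f"g{i}" for i in range(20)])
        res = cluster_degs(df)
        expected = _average_linkage_oracle(X)
        assert np.allclose(sorted(res.linkage[:, 2]), sorted(expected),
                           atol=1e-9)
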