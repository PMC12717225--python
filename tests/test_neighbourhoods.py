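"""Radius graphs, neighbourhood matrices, Leiden clusters, enrichment test."""

import numpy as np
import pandas as pd
import pytest

from plaquespace import neighbourhoods as nb

from _oracles import (
    brute_force_pair_scores,
    brute_force_radius_edges,
    exhaustive_enrichment_null,
)
from conftest import make_cells


def chain_cells(labels, spacing=90.0, sample_id="S0"):
    xy = [(i * spacing, 0.0) for i in range(len(labels))]
    return make_cells(xy, labels, sample_id=sample_id)


class TestRadiusGraph:
    def test_single_cell_no_edges(self):
        g = nb.radius_graph(make_cells([[0, 0]], "A"))
        assert len(g.edges) == 0

    def test_line_example(self):
        cells = make_cells([[0, 0], [90, 0], [180, 0], [500, 0]], "AAAA")
        g = nb.radius_graph(cells, radius_um=100)
        assert g.edges.tolist() == [[0, 1], [1, 2]]

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            xy = rng.uniform(0, 600, size=(300, 2))
            cells = make_cells(xy, ["A"] * 300)
            g = nb.radius_graph(cells, radius_um=100)
            assert set(map(tuple, g.edges)) == brute_force_radius_edges(xy, 100)

    def test_boundary_distance_included(self):
        cells = make_cells([[0, 0], [100, 0]], "AB")
        g = nb.radius_graph(cells, radius_um=100)
        assert len(g.edges) == 1


class TestNeighbourhoodMatrix:
    def test_chain_example(self):
        cells = chain_cells("ABA")
        g = nb.radius_graph(cells, radius_um=100)
        M = nb.neighbourhood_matrix(cells, g)
        assert M.iloc[0].to_dict() == {"A": 0, "B": 1}
        assert M.iloc[1].to_dict() == {"A": 2, "B": 0}
        assert M.iloc[2].to_dict() == {"A": 0, "B": 1}

    def test_isolated_cell_zero_row(self):
        cells = make_cells([[0, 0], [1000, 0]], "AB")
        g = nb.radius_graph(cells, radius_um=100)
        M = nb.neighbourhood_matrix(cells, g)
        assert (M.sum(axis=1) == 0).all()

    def test_row_sums_equal_degrees(self):
        rng = np.random.default_rng(1)
        cells = make_cells(rng.uniform(0, 500, (200, 2)), rng.choice(list("ABC"), 200))
        g = nb.radius_graph(cells)
        M = nb.neighbourhood_matrix(cells, g)
        np.testing.assert_array_equal(M.sum(axis=1).to_numpy(), g.degrees())

    def test_matches_per_cell_brute_force(self):
        rng = np.random.default_rng(2)
        xy = rng.uniform(0, 400, size=(100, 2))
        labels = rng.choice(list("AB"), 100)
        cells = make_cells(xy, labels)
        g = nb.radius_graph(cells)
        M = nb.neighbourhood_matrix(cells, g)
        for i in range(100):
            for s in "AB":
                expected = sum(
                    1
                    for j in range(100)
                    if j != i
                    and labels[j] == s
                    and np.hypot(*(xy[i] - xy[j])) <= 100
                )
                assert M.iloc[i][s] == expected


class TestClusterNeighbourhoods:
    def test_identical_vectors_single_cluster(self):
        M = pd.DataFrame(
            np.ones((30, 3)), index=[f"c{i}" for i in range(30)], columns=list("ABC")
        )
        cl = nb.cluster_neighbourhoods(M, knn_k=5, seed=0)
        assert cl.labels.nunique() == 1

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(3)
        M = pd.DataFrame(
            rng.poisson(3, size=(120, 4)),
            index=[f"c{i}" for i in range(120)],
            columns=list("ABCD"),
        )
        a = nb.cluster_neighbourhoods(M, knn_k=10, seed=5)
        b = nb.cluster_neighbourhoods(M, knn_k=10, seed=5)
        assert (a.labels == b.labels).all()

    def test_signatures_recompute_exactly(self):
        rng = np.random.default_rng(4)
        M = pd.DataFrame(
            rng.poisson(2, size=(100, 3)),
            index=[f"c{i}" for i in range(100)],
            columns=list("ABC"),
        )
        cl = nb.cluster_neighbourhoods(M, knn_k=8, seed=1)
        recomputed = M.groupby(cl.labels).mean()
        pd.testing.assert_frame_equal(cl.signatures, recomputed, check_names=False)

    def test_too_few_cells_rejected(self):
        M = pd.DataFrame(np.ones((5, 2)), index=[f"c{i}" for i in range(5)])
        with pytest.raises(ValueError):
            nb.cluster_neighbourhoods(M, knn_k=10)


class TestEnrichmentScore:
    def test_chain_example_with_isolated_cell(self):
        cells = make_cells([[0, 0], [90, 0], [180, 0], [900, 0]], "ABAB")
        g = nb.radius_graph(cells, radius_um=100)
        labels = pd.Series(cells["substate"].to_numpy(), index=cells["cell_id"])
        scores = nb.enrichment_score(g, labels, set(cells["cell_id"]))
        assert scores[("A", "B")] == 2
        assert scores[("A", "A")] == 0
        assert scores[("B", "B")] == 0

    def test_empty_cluster_all_zero(self):
        cells = chain_cells("AB")
        g = nb.radius_graph(cells)
        labels = pd.Series(cells["substate"].to_numpy(), index=cells["cell_id"])
        scores = nb.enrichment_score(g, labels, set())
        assert all(v == 0 for v in scores.values())

    def test_matches_brute_force_and_conserves(self):
        rng = np.random.default_rng(5)
        xy = rng.uniform(0, 400, size=(150, 2))
        labels_arr = rng.choice(list("ABC"), 150)
        cells = make_cells(xy, labels_arr)
        g = nb.radius_graph(cells)
        labels = pd.Series(labels_arr, index=cells["cell_id"])
        members = set(cells["cell_id"][:100])
        scores = nb.enrichment_score(g, labels, members)
        member_idx = set(range(100))
        kept_edges = [
            (i, j) for i, j in g.edges if i in member_idx and j in member_idx
        ]
        oracle = brute_force_pair_scores(kept_edges, labels_arr)
        for pair, v in scores.items():
            assert v == oracle.get(pair, 0)
        assert sum(scores.values()) == len(kept_edges)


class TestMonteCarloPvalues:
    def test_forced_values(self):
        pl, pr, pt = nb.monte_carlo_pvalues(3, 0, 3)
        assert (pl, pr, pt) == (1.0, 0.25, 0.5)
        pl, pr, pt = nb.monte_carlo_pvalues(0, 0, 10)
        assert pl == pytest.approx(1 / 11)
        assert pr == pytest.approx(1 / 11)
        assert pt == pytest.approx(2 / 11)

    def test_never_zero_and_capped(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            N = int(rng.integers(1, 50))
            l = int(rng.integers(0, N + 1))
            r = int(rng.integers(0, N + 1 - l))
            pl, pr, pt = nb.monte_carlo_pvalues(l, r, N)
            assert 0 < pl <= 1 and 0 < pr <= 1 and 0 < pt <= 1


class TestPermutationTest:
    def test_converges_to_exhaustive_enumeration(self):
        cells = make_cells([[0, 0], [50, 0], [100, 0], [150, 0]], "AABB")
        g = nb.build_graphs(cells, radius_um=60)
        clusters = pd.Series(0, index=cells["cell_id"])
        N = 2000
        rep = nb.permutation_test(cells, g, clusters, n_permutations=N, seed=0)
        edges = g["S0"].edges.tolist()
        nulls = exhaustive_enrichment_null(edges, list("AABB"))
        obs = brute_force_pair_scores(edges, list("AABB"))
        for _, row in rep.iterrows():
            pair = (row["substate_a"], row["substate_b"])
            o = obs.get(pair, 0)
            frac_l = np.mean([n.get(pair, 0) < o for n in nulls])
            frac_r = np.mean([n.get(pair, 0) > o for n in nulls])
            for p_mc, frac in ((row["p_left"], frac_l), (row["p_right"], frac_r)):
                p_exact = (frac * N + 1) / (N + 1)
                se = np.sqrt(max(frac * (1 - frac), 1e-12) / N) + 1e-9
                assert abs(p_mc - p_exact) <= 3 * se + 2 / (N + 1)

    def test_scores_conserve_per_cluster(self):
        rng = np.random.default_rng(6)
        cells = make_cells(rng.uniform(0, 400, (120, 2)), rng.choice(list("AB"), 120))
        g = nb.build_graphs(cells)
        clusters = pd.Series(
            rng.integers(0, 2, 120), index=cells["cell_id"]
        )
        rep = nb.permutation_test(cells, g, clusters, n_permutations=10, seed=1)
        for c in (0, 1):
            members = set(clusters[clusters == c].index)
            scores = nb.enrichment_score(g["S0"], cells.set_index("cell_id")["substate"], members)
            sub = rep[rep["cluster"] == c]
            assert sub["observed"].sum() == sum(scores.values())

    def test_shuffling_respects_sample_boundaries(self):
        # two samples with disjoint label alphabets: permutations never mix them,
        # so within-sample label multisets are preserved and scores for
        # cross-alphabet pairs have degenerate nulls
        a = make_cells([[0, 0], [50, 0]], "AA", sample_id="S0")
        b = make_cells([[0, 0], [50, 0]], "BB", sample_id="S1")
        cells = pd.concat([a, b], ignore_index=True)
        g = nb.build_graphs(cells, radius_um=60)
        clusters = pd.Series(0, index=cells["cell_id"])
        rep = nb.permutation_test(cells, g, clusters, n_permutations=50, seed=2)
        row_ab = rep[(rep["substate_a"] == "A") & (rep["substate_b"] == "B")].iloc[0]
        assert row_ab["observed"] == 0 and row_ab["l"] == 0 and row_ab["r"] == 0

    def test_reproducible_under_seed(self):
        rng = np.random.default_rng(7)
        cells = make_cells(rng.uniform(0, 300, (60, 2)), rng.choice(list("AB"), 60))
        g = nb.build_graphs(cells)
        clusters = pd.Series(0, index=cells["cell_id"])
        r1 = nb.permutation_test(cells, g, clusters, n_permutations=100, seed=9)
        r2 = nb.permutation_test(cells, g, clusters, n_permutations=100, seed=9)
        pd.testing.assert_frame_equal(r1, r2)

    def test_planted_adjacent_pair_detected(self):
        """Two substates planted intermixed in a tight block reach FDR < 0.05."""
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(100 + seed)
            block = rng.uniform(0, 150, size=(60, 2))
            rest = rng.uniform(300, 1200, size=(90, 2))
            labels = list(rng.permutation(["A"] * 30 + ["B"] * 30)) + list(
                rng.choice(list("CD"), 90)
            )
            cells = make_cells(np.vstack([block, rest]), labels)
            g = nb.build_graphs(cells)
            clusters = pd.Series(
                [0] * 60 + [1] * 90, index=cells["cell_id"]
            )
            rep = nb.permutation_test(cells, g, clusters, n_permutations=1000, seed=seed)
            row = rep[
                (rep["cluster"] == 0)
                & (rep["substate_a"] == "A")
                & (rep["substate_b"] == "B")
            ].iloc[0]
            hits += row["fdr"] < 0.05
        assert hits >= 0.95 * n_seeds


class TestAgrestiCoull:
    def test_direct_formula(self):
        lo, hi = nb.agresti_coull_ci(2, 8, z=2.0)
        p_t = (2 + 2) / 12
        half = 2 * np.sqrt(p_t * (1 - p_t) / 12)
        assert lo == pytest.approx(p_t - half)
        assert hi == pytest.approx(p_t + half)

    def test_zero_count_clipped(self):
        lo, hi = nb.agresti_coull_ci(0, 10)
        assert lo >= 0.0 and hi <= 1.0

    def test_coverage_at_small_p(self):
        rng = np.random.default_rng(8)
        n, p = 999, 0.05
        xs = rng.binomial(n, p, size=1000)
        lo, hi = nb.agresti_coull_ci(xs, n)
        coverage = np.mean((lo <= p) & (p <= hi))
        assert coverage >= 0.93

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            nb.agresti_coull_ci(1, 0)
        with pytest.raises(ValueError):
            nb.agresti_coull_ci(11, 10)
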