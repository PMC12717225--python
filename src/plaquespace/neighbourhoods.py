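"""Cellular-neighbourhood analysis: the pipeline's core machinery.

A radius graph (closed 100 µm ball by default) connects cells within each
sample.  Per-cell neighbourhood matrices count each substate among a cell's
neighbours (focal cell excluded).  Leiden community detection on a KNN graph
of those count vectors yields neighbourhood clusters shared across samples.
The enrichment statistic for a cluster is, per unordered substate pair
{s, t} (including s = t), the number of unique undirected edges of the
cluster-restricted graph joining an s-cell to a t-cell.  Its null
distribution comes from shuffling substate labels within samples while
holding coordinates, edges and cluster memberships fixed; p-values use the
add-one Monte-Carlo rule

    p_left = (l + 1) / (N + 1),   p_right = (r + 1) / (N + 1)

with l = #{null < observed} and r = #{null > observed},
p_two = min(2 p_left, 2 p_right) capped at 1, Agresti-Coull intervals for
the left/right proportions combined endpoint-wise by the same min-rule, and
BH FDR across all (cluster, pair) tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph
import leidenalg
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.neighbors import NearestNeighbors

from plaquespace.composition import bh_adjust

DEFAULT_RADIUS_UM = 100.0


@dataclass
class SpatialGraph:
    """Undirected radius graph over the cells of one sample.

    ``edges`` is an (E, 2) array of positional indices into ``cell_ids``
    with edges[:, 0] < edges[:, 1]; no self-loops, no duplicates.
    """

    sample_id: str
    cell_ids: np.ndarray
    edges: np.ndarray
    radius_um: float

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_cells, dtype=int)
        np.add.at(deg, self.edges.ravel(), 1)
        return deg


def radius_graph(cells: pd.DataFrame, radius_um: float = DEFAULT_RADIUS_UM) -> SpatialGraph:
    """Connect all cell pairs of one sample at Euclidean distance <= radius."""
    sids = pd.unique(cells["sample_id"])
    if len(sids) != 1:
        raise ValueError("radius_graph expects cells of a single sample")
    xy = cells[["x_um", "y_um"]].to_numpy()
    if not np.isfinite(xy).all():
        raise ValueError("non-finite coordinates")
    pairs = cKDTree(xy).query_pairs(r=radius_um, output_type="ndarray")
    if pairs.size == 0:
        pairs = np.empty((0, 2), dtype=int)
    pairs = np.sort(pairs, axis=1)
    pairs = pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]
    return SpatialGraph(
        sample_id=str(sids[0]),
        cell_ids=cells["cell_id"].to_numpy(),
        edges=pairs,
        radius_um=radius_um,
    )


def build_graphs(cells: pd.DataFrame, radius_um: float = DEFAULT_RADIUS_UM) -> dict[str, SpatialGraph]:
    """Per-sample radius graphs, keyed by sample id."""
    return {
        str(sid): radius_graph(group, radius_um)
        for sid, group in cells.groupby("sample_id", sort=True)
    }


def neighbourhood_matrix(
    cells: pd.DataFrame, graphs: SpatialGraph | dict[str, SpatialGraph]
) -> pd.DataFrame:
    """Cells x substates neighbour counts (focal cell excluded).

    Rows are indexed by cell id in the input order; columns span all
    substates present anywhere in ``cells``, so matrices from different
    samples are directly stackable.  Isolated cells get all-zero rows.
    """
    if cells["substate"].isna().any():
        raise ValueError("every cell needs a substate label")
    if isinstance(graphs, SpatialGraph):
        graphs = {graphs.sample_id: graphs}
    substates = np.array(sorted(pd.unique(cells["substate"].astype(str))))
    code_of = {s: i for i, s in enumerate(substates)}
    out = np.zeros((len(cells), len(substates)), dtype=int)
    row_of = pd.Series(np.arange(len(cells)), index=cells["cell_id"])
    for sid, g in graphs.items():
        rows = row_of[g.cell_ids].to_numpy()
        codes = np.array(
            [code_of[s] for s in cells["substate"].to_numpy()[rows]]
        )
        i, j = g.edges[:, 0], g.edges[:, 1]
        np.add.at(out, (rows[i], codes[j]), 1)
        np.add.at(out, (rows[j], codes[i]), 1)
    return pd.DataFrame(out, index=pd.Index(cells["cell_id"], name="cell_id"), columns=substates)


@dataclass
class NeighbourhoodClusters:
    """Leiden labels per cell plus cluster signatures.

    ``signatures`` row c is the mean neighbourhood count vector of cells in
    cluster c — the composition fingerprint of the spatial domain.
    """

    labels: pd.Series
    signatures: pd.DataFrame
    knn_k: int
    resolution: float
    seed: int


def cluster_neighbourhoods(
    matrix: pd.DataFrame,
    knn_k: int = 15,
    resolution: float = 1.0,
    seed: int = 0,
    log1p: bool = False,
) -> NeighbourhoodClusters:
    """Leiden clustering of neighbourhood count vectors.

    Builds an exact Euclidean k-nearest-neighbour graph on the (optionally
    log1p-transformed) count vectors pooled across samples, symmetrises it,
    and runs Leiden (RB modularity) at the given resolution and seed.
    Identical neighbourhood vectors are indistinguishable, so duplicates are
    collapsed before graph construction and always share a cluster.
    """
    X = matrix.to_numpy(dtype=float)
    if log1p:
        X = np.log1p(X)
    n = len(X)
    if n < knn_k + 1:
        raise ValueError("fewer cells than knn_k + 1")
    uniq, inverse = np.unique(X, axis=0, return_inverse=True)
    n_u = len(uniq)
    if n_u == 1:
        membership = np.zeros(n_u, dtype=int)
    else:
        k_eff = min(knn_k, n_u - 1)
        nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(uniq)
        _, idx = nn.kneighbors(uniq)
        src = np.repeat(np.arange(n_u), k_eff)
        dst = idx[:, 1:].ravel()  # drop self
        und = np.unique(np.sort(np.column_stack([src, dst]), axis=1), axis=0)
        g = igraph.Graph(n=n_u, edges=und.tolist(), directed=False)
        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=resolution,
            seed=seed,
            n_iterations=2,
        )
        membership = np.array(part.membership)
    labels = pd.Series(membership[inverse], index=matrix.index, name="nbhd_cluster")
    signatures = matrix.groupby(labels).mean()
    signatures.index.name = "nbhd_cluster"
    return NeighbourhoodClusters(labels, signatures, knn_k, resolution, seed)


def _pair_codes(n_substates: int) -> tuple[np.ndarray, list[tuple[int, int]]]:
    # map (min, max) substate code pairs to a compact index
    pairs = [(i, j) for i in range(n_substates) for j in range(i, n_substates)]
    lut = np.full((n_substates, n_substates), -1, dtype=int)
    for k, (i, j) in enumerate(pairs):
        lut[i, j] = lut[j, i] = k
    return lut, pairs


def enrichment_score(
    graph: SpatialGraph, labels: pd.Series, cluster_members
) -> dict[tuple[str, str], int]:
    """Edge counts per unordered substate pair within one cluster's subgraph.

    Restricts the sample graph to ``cluster_members`` and counts, for every
    unordered substate pair {s, t} (s may equal t), the unique undirected
    edges whose endpoint labels are {s, t}.  The counts sum to the number of
    within-cluster edges.
    """
    members = set(cluster_members)
    lab = labels[graph.cell_ids].to_numpy().astype(str)
    in_cluster = np.array([c in members for c in graph.cell_ids])
    substates = np.array(sorted(set(lab)))
    code_of = {s: i for i, s in enumerate(substates)}
    codes = np.array([code_of[s] for s in lab])
    keep = in_cluster[graph.edges[:, 0]] & in_cluster[graph.edges[:, 1]]
    e = graph.edges[keep]
    lut, pairs = _pair_codes(len(substates))
    scores = np.bincount(lut[codes[e[:, 0]], codes[e[:, 1]]], minlength=len(pairs))
    return {
        (substates[i], substates[j]): int(scores[k]) for k, (i, j) in enumerate(pairs)
    }


def permutation_test(
    cells: pd.DataFrame,
    graphs: dict[str, SpatialGraph],
    clusters: pd.Series,
    n_permutations: int = 10_000,
    seed: int = 0,
    fdr_threshold: float = 0.05,
    z: float = 1.96,
) -> pd.DataFrame:
    """Within-sample label-shuffling test of neighbourhood enrichment.

    For every (neighbourhood cluster, unordered substate pair) the observed
    enrichment score is compared against ``n_permutations`` scores computed
    after independently permuting substate labels within each sample
    (coordinates, edges and cluster memberships fixed).  Null scores are
    streamed: only the exceedance counters l and r are kept.  Per-permutation
    child RNGs are derived from (seed, permutation index), so results are
    reproducible and order-independent.

    Returns a tidy frame with one row per (cluster, substate_a, substate_b):
    observed, l, r, p_left, p_right, p_two, ci_lo, ci_hi, fdr, significant.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    cells = cells.reset_index(drop=True)
    labels_all = cells["substate"].astype(str).to_numpy()
    substates = np.array(sorted(set(labels_all)))
    code_of = {s: i for i, s in enumerate(substates)}
    codes_all = np.array([code_of[s] for s in labels_all])
    row_of = pd.Series(np.arange(len(cells)), index=cells["cell_id"])
    clu = clusters[cells["cell_id"]].to_numpy()
    cluster_ids = np.array(sorted(pd.unique(clu)))
    lut, pairs = _pair_codes(len(substates))
    n_pairs = len(pairs)

    # per-cluster concatenated edge endpoints (global row indices)
    cluster_edges: list[tuple[np.ndarray, np.ndarray]] = []
    for c in cluster_ids:
        ei_parts, ej_parts = [], []
        for g in graphs.values():
            rows = row_of[g.cell_ids].to_numpy()
            keep = (clu[rows[g.edges[:, 0]]] == c) & (clu[rows[g.edges[:, 1]]] == c)
            e = g.edges[keep]
            ei_parts.append(rows[e[:, 0]])
            ej_parts.append(rows[e[:, 1]])
        cluster_edges.append(
            (np.concatenate(ei_parts), np.concatenate(ej_parts))
            if ei_parts
            else (np.empty(0, dtype=int), np.empty(0, dtype=int))
        )

    def scores_for(codes: np.ndarray) -> np.ndarray:
        out = np.empty((len(cluster_ids), n_pairs), dtype=np.int64)
        for ci, (ei, ej) in enumerate(cluster_edges):
            out[ci] = np.bincount(lut[codes[ei], codes[ej]], minlength=n_pairs)
        return out

    observed = scores_for(codes_all)
    l = np.zeros_like(observed)
    r = np.zeros_like(observed)

    sample_rows = [
        row_of[g.cell_ids].to_numpy() for g in graphs.values()
    ]
    perm_codes = codes_all.copy()
    for b in range(n_permutations):
        rng = np.random.default_rng(np.random.SeedSequence([seed, b]))
        for rows in sample_rows:
            perm_codes[rows] = codes_all[rows][rng.permutation(len(rows))]
        null = scores_for(perm_codes)
        l += null < observed
        r += null > observed

    N = n_permutations
    p_left, p_right, p_two = monte_carlo_pvalues(l, r, N)
    lo_l, hi_l = agresti_coull_ci(l, N, z)
    lo_r, hi_r = agresti_coull_ci(r, N, z)
    ci_lo = np.minimum(np.minimum(2 * lo_l, 2 * lo_r), 1.0)
    ci_hi = np.minimum(np.minimum(2 * hi_l, 2 * hi_r), 1.0)

    rows_out = []
    for ci, c in enumerate(cluster_ids):
        for k, (i, j) in enumerate(pairs):
            rows_out.append(
                {
                    "cluster": c,
                    "substate_a": substates[i],
                    "substate_b": substates[j],
                    "observed": int(observed[ci, k]),
                    "l": int(l[ci, k]),
                    "r": int(r[ci, k]),
                    "p_left": p_left[ci, k],
                    "p_right": p_right[ci, k],
                    "p_two": p_two[ci, k],
                    "ci_lo": ci_lo[ci, k],
                    "ci_hi": ci_hi[ci, k],
                }
            )
    report = pd.DataFrame(rows_out)
    report["fdr"] = bh_adjust(report["p_two"].to_numpy())
    report["significant"] = report["fdr"] < fdr_threshold
    return report


def monte_carlo_pvalues(l, r, n_permutations: int):
    """Add-one Monte-Carlo p-values from strict exceedance counts.

    l = #{null < observed}, r = #{null > observed}.  Returns
    (p_left, p_right, p_two) with p_left = (l+1)/(N+1),
    p_right = (r+1)/(N+1), p_two = min(2 p_left, 2 p_right, 1).  None of
    them can be zero.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    l = np.asarray(l, dtype=float)
    r = np.asarray(r, dtype=float)
    N = n_permutations
    p_left = (l + 1) / (N + 1)
    p_right = (r + 1) / (N + 1)
    p_two = np.minimum(np.minimum(2 * p_left, 2 * p_right), 1.0)
    return p_left, p_right, p_two


def agresti_coull_ci(x, n: int, z: float = 1.96):
    """Agresti-Coull interval for a binomial proportion, clipped to [0, 1].

    n~ = n + z², p~ = (x + z²/2) / n~, half-width z * sqrt(p~ (1 - p~) / n~).
    """
    if n == 0:
        raise ValueError("n must be positive")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x > n):
        raise ValueError("x must lie in [0, n]")
    n_t = n + z**2
    p_t = (x + z**2 / 2) / n_t
    half = z * np.sqrt(p_t * (1 - p_t) / n_t)
    return np.clip(p_t - half, 0.0, 1.0), np.clip(p_t + half, 0.0, 1.0)


def ci_two_sided(
    lo_left: float, hi_left: float, lo_right: float, hi_right: float
) -> tuple[float, float]:
    """Endpoint-wise min-rule for the two-sided interval, capped at 1."""
    return (
        min(2 * lo_left, 2 * lo_right, 1.0),
        min(2 * hi_left, 2 * hi_right, 1.0),
    )
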