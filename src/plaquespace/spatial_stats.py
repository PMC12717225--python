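"""Local spatial statistics on binarized cell-identity patterns.

Local bivariate Moran's I with row-standardized KNN weights (k = 30) for
substate colocalization, and local Getis-Ord G with binary distance-band
weights (2500 µm) for hotspot detection, both with conditional permutation
nulls (the focal cell's value is held fixed; all other values are permuted)
and add-one Monte-Carlo p-values.  Variables are z-standardized with the
population SD.  Moran p-values are one-sided (upper tail: positive local
association), Getis-Ord p-values two-sided; the asymmetry mirrors how the
two analyses are conventionally reported.

Note the bivariate statistic is not symmetric in its arguments: I(x, y)
measures x at the focal cell against the spatial lag of y, so swapping x
and y changes the result.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from plaquespace.composition import bh_adjust

logger = logging.getLogger(__name__)


def binarize(labels, target: str) -> np.ndarray:
    """Indicator vector: 1 where the label equals ``target``."""
    lab = np.asarray(labels).astype(str)
    out = (lab == target).astype(float)
    if out.sum() == 0:
        logger.warning("target substate %r absent; all-zero indicator", target)
    return out


def knn_neighbours(coords: np.ndarray, k: int = 30) -> np.ndarray:
    """(n, k') matrix of nearest-neighbour indices, self excluded.

    k' = min(k, n - 1): tiny samples use all available neighbours.  Exact
    ties in distance resolve to the lower index.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    k_eff = min(k, n - 1)
    if k_eff < 1:
        raise ValueError("need at least two cells")
    _, idx = cKDTree(coords).query(coords, k=k_eff + 1)
    idx = np.atleast_2d(idx)
    # drop self (first column after sorting by distance; ties keep lower id)
    out = np.empty((n, k_eff), dtype=int)
    for i in range(n):
        row = idx[i]
        out[i] = row[row != i][:k_eff]
    return out


def band_neighbours(coords: np.ndarray, radius_um: float) -> list[np.ndarray]:
    """Per-cell indices of cells within ``radius_um`` (self excluded)."""
    coords = np.asarray(coords, dtype=float)
    tree = cKDTree(coords)
    lists = tree.query_ball_point(coords, r=radius_um)
    return [np.array([j for j in lst if j != i], dtype=int) for i, lst in enumerate(lists)]


def _zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std()  # population SD
    if sd == 0:
        raise ValueError("zero variance")
    return (x - x.mean()) / sd


def _conditional_draws(rng, n: int, permutations: int, kmax: int) -> np.ndarray:
    """(permutations, kmax) positions into each cell's shuffled 'others' list.

    One shared position matrix, sampled without replacement per permutation
    — the classical conditional-randomization scheme for local statistics.
    """
    pos = np.tile(np.arange(n - 1), (permutations, 1))
    pos = rng.permuted(pos, axis=1)
    return pos[:, :kmax]


def local_bivariate_moran(
    x,
    y,
    coords,
    k: int = 30,
    permutations: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Local bivariate Moran's I per cell with conditional permutation p.

    I_i = z_x,i * sum_j w_ij z_y,j with row-standardized KNN weights.  The
    null shuffles y over all cells except i while holding x_i fixed;
    p = (#{null >= observed} + 1) / (permutations + 1), one-sided for
    positive local association.  Quadrants (HH/HL/LH/LL) come from the signs
    of z_x,i and the spatial lag.
    """
    coords = np.asarray(coords, dtype=float)
    z_x, z_y = _zscore(x), _zscore(y)
    n = len(z_x)
    nbrs = knn_neighbours(coords, k)
    k_eff = nbrs.shape[1]
    lag = z_y[nbrs].mean(axis=1)
    I = z_x * lag

    rng = np.random.default_rng(seed)
    draws = _conditional_draws(rng, n, permutations, k_eff)
    ids = np.arange(n)
    p = np.empty(n)
    for i in range(n):
        others = ids[ids != i]
        rng.shuffle(others)
        null_lag = z_y[others[draws]].mean(axis=1)
        null_I = z_x[i] * null_lag
        p[i] = (np.sum(null_I >= I[i]) + 1) / (permutations + 1)

    quadrant = np.where(
        z_x > 0, np.where(lag > 0, "HH", "HL"), np.where(lag > 0, "LH", "LL")
    )
    out = pd.DataFrame(
        {"I": I, "p": p, "fdr": bh_adjust(p), "category": quadrant}
    )
    return out


def local_getis_ord(
    x,
    coords,
    band_radius_um: float = 2500.0,
    permutations: int = 999,
    seed: int = 0,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Local Getis-Ord G per cell with conditional permutation p (two-sided).

    G_i = sum_{j in band(i)} x_j / sum_{j != i} x_j (plain G: the focal cell
    is excluded from both sums).  The denominator is permutation-invariant,
    so the null only redraws which values fall in the band.  Cells whose
    denominator is zero get a missing statistic with a warning.  Hot: G
    above its null mean and FDR < threshold; cold: below and significant.
    """
    coords = np.asarray(coords, dtype=float)
    x = np.asarray(x, dtype=float)
    n = len(x)
    if x.sum() == 0:
        raise ValueError("x has no positive entries")
    nbrs = band_neighbours(coords, band_radius_um)
    total = x.sum()
    denom = total - x
    G = np.full(n, np.nan)
    p = np.full(n, np.nan)
    null_mean = np.full(n, np.nan)

    rng = np.random.default_rng(seed)
    kmax = max((len(b) for b in nbrs), default=0)
    draws_full = _conditional_draws(rng, n, permutations, kmax) if kmax else None
    ids = np.arange(n)
    for i in range(n):
        if denom[i] == 0:
            logger.warning("cell %d: no other positive values; G undefined", i)
            continue
        b = nbrs[i]
        if len(b) == 0:
            G[i] = 0.0
        else:
            G[i] = x[b].sum() / denom[i]
        k_i = len(b)
        if k_i == 0:
            null = np.zeros(permutations)
        else:
            others = ids[ids != i]
            rng.shuffle(others)
            null = x[others[draws_full[:, :k_i]]].sum(axis=1) / denom[i]
        null_mean[i] = null.mean()
        p_le = (np.sum(null <= G[i]) + 1) / (permutations + 1)
        p_ge = (np.sum(null >= G[i]) + 1) / (permutations + 1)
        p[i] = min(1.0, 2 * min(p_le, p_ge))

    ok = ~np.isnan(p)
    fdr = np.full(n, np.nan)
    if ok.any():
        fdr[ok] = bh_adjust(p[ok])
    category = np.full(n, "ns", dtype=object)
    sig = ok & (fdr < fdr_threshold)
    category[sig & (G > null_mean)] = "hot"
    category[sig & (G < null_mean)] = "cold"
    return pd.DataFrame({"G": G, "p": p, "fdr": fdr, "category": category})


def marker_expression_contrast(
    expr: pd.DataFrame,
    group_mask,
    genes: list[str] | None = None,
    sample_ids=None,
) -> pd.DataFrame:
    """Rank-sum contrast of marker expression: one substate vs all others.

    ``expr`` is cells x genes (normalized expression); ``group_mask`` marks
    the target-substate cells.  Tests run per (gene, sample) when
    ``sample_ids`` is given, else per gene, two-sided, with BH across the
    whole family.  Samples where either group is empty are skipped with a
    warning.
    """
    mask = np.asarray(group_mask, dtype=bool)
    genes = list(genes) if genes is not None else list(expr.columns)
    strata = (
        pd.Series(np.asarray(sample_ids))
        if sample_ids is not None
        else pd.Series(["all"] * len(expr))
    )
    rows = []
    for sid in pd.unique(strata):
        sel = (strata == sid).to_numpy()
        m = mask[sel]
        if m.sum() == 0 or (~m).sum() == 0:
            logger.warning("sample %s: one group empty; skipped", sid)
            continue
        sub = expr.loc[sel, genes]
        for gene in genes:
            v = sub[gene].to_numpy()
            p = stats.mannwhitneyu(v[m], v[~m], alternative="two-sided").pvalue
            rows.append({"sample_id": sid, "gene": gene, "p": float(p)})
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = bh_adjust(out["p"].to_numpy())
    return out
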