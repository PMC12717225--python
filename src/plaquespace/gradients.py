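"""Macrophage layering and expression-gradient analysis.

Per-sample min-max normalization of area-normalized expression, substate
mean profiles, top-variance gene selection, per-gene Z-scoring across
substates, distance-to-lumen computation and the normalized-distance
layering order of substates.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import shapely

from plaquespace.types import GeometryError, SubregionAnnotation

logger = logging.getLogger(__name__)


def minmax_normalize(expr: pd.DataFrame, sample_ids) -> pd.DataFrame:
    """Min-max normalize each gene within each sample to [0, 1].

    Input should be area-normalized expression (cells x genes).  A gene
    constant within a sample maps to all zeros so profiles stay finite.
    """
    strata = pd.Series(np.asarray(sample_ids), index=expr.index)
    out = expr.copy().astype(float)
    for sid, idx in strata.groupby(strata).groups.items():
        block = out.loc[idx]
        lo = block.min(axis=0)
        span = block.max(axis=0) - lo
        span_safe = span.replace(0, 1.0)
        norm = (block - lo) / span_safe
        norm.loc[:, span == 0] = 0.0
        out.loc[idx] = norm
    return out


def substate_mean_profiles(
    expr: pd.DataFrame, labels, substates: list[str]
) -> pd.DataFrame:
    """Mean normalized expression per substate (rows) per gene (columns)."""
    lab = pd.Series(np.asarray(labels).astype(str), index=expr.index)
    rows = {}
    for s in substates:
        sel = lab == s
        if not sel.any():
            raise ValueError(f"substate {s!r} has no cells")
        rows[s] = expr.loc[sel.to_numpy()].mean(axis=0)
    out = pd.DataFrame(rows).T
    out.index.name = "substate"
    return out


def top_variance_genes(profiles: pd.DataFrame, n: int = 20) -> list[str]:
    """Genes with the highest variance of mean expression across substates.

    Ties broken by gene name (ascending) for determinism.
    """
    if n > profiles.shape[1]:
        raise ValueError("n exceeds the number of genes")
    var = profiles.var(axis=0, ddof=0)
    order = sorted(profiles.columns, key=lambda g: (-var[g], g))
    return order[:n]


def zscore_profiles(profiles: pd.DataFrame) -> pd.DataFrame:
    """Z-score each gene across substates (population SD; constants -> 0)."""
    if len(profiles) < 2:
        raise ValueError("need at least two substates")
    mean = profiles.mean(axis=0)
    sd = profiles.std(axis=0, ddof=0)
    sd_safe = sd.replace(0, 1.0)
    z = (profiles - mean) / sd_safe
    z.loc[:, sd == 0] = 0.0
    return z


def lumen_distance(
    cells: pd.DataFrame,
    polygons: list[SubregionAnnotation],
    cap: float = 0.25,
) -> pd.DataFrame:
    """Distance of each cell to the lumen, normalized within the sample.

    Raw distance is the Euclidean distance from the cell centroid to the
    nearest lumen polygon (0 for cells inside a lumen polygon; with several
    lumen fragments, the nearest one counts).  Normalized distance is raw
    divided by the sample's maximum raw distance; ``included`` flags cells
    with normalized distance <= ``cap`` (the subluminal zone).
    """
    lumens = [p for p in polygons if p.region == "lumen"]
    if not lumens:
        raise GeometryError("no lumen polygon in sample")
    geoms = [p.to_shapely() for p in lumens]
    pts = shapely.points(cells["x_um"].to_numpy(), cells["y_um"].to_numpy())
    raw = np.min(
        np.stack([shapely.distance(pts, g) for g in geoms]), axis=0
    )
    max_raw = raw.max()
    norm = raw / max_raw if max_raw > 0 else np.zeros_like(raw)
    return pd.DataFrame(
        {
            "cell_id": cells["cell_id"].to_numpy(),
            "raw_um": raw,
            "normalized": norm,
            "included": norm <= cap,
        }
    )


def layering_order(
    distances: pd.DataFrame, labels, substates: list[str]
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Median normalized lumen distance per substate, ranked ascending.

    Only cells with ``included`` set (normalized distance within the cap)
    contribute.  Substates with no included cells are excluded with a
    warning.  Returns the ranking table and the per-substate distance
    samples for density plotting.
    """
    lab = np.asarray(labels).astype(str)
    rows = []
    samples: dict[str, np.ndarray] = {}
    for s in substates:
        sel = (lab == s) & distances["included"].to_numpy()
        if not sel.any():
            logger.warning("substate %r has no included cells; excluded", s)
            continue
        d = distances.loc[sel, "normalized"].to_numpy()
        samples[s] = d
        rows.append({"substate": s, "median_normalized": float(np.median(d)), "n": int(sel.sum())})
    out = pd.DataFrame(rows).sort_values("median_normalized").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out, samples
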