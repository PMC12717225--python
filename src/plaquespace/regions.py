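"""Tissue-subregion geometry and per-region noise accounting.

Polygon areas (shoelace via shapely), normalized region areas, point-in-
polygon assignment of cells to subregions with an anatomical priority order,
per-region noise-transcript ratios, and the Mann-Whitney-U + BH machinery
for comparing region statistics between sample groups.

Polygons are treated as closed sets: a point on the boundary is inside.
Where regions overlap (digitization slivers), priority is
lumen > thrombus > necrotic_core > fibrous_cap > intima > media.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import shapely
from scipy.stats import mannwhitneyu

from plaquespace.composition import bh_adjust
from plaquespace.types import (
    GeometryError,
    REGION_PRIORITY,
    SubregionAnnotation,
    is_noise,
)

UNASSIGNED = "unassigned"


def polygon_area(polygon: SubregionAnnotation) -> float:
    """Absolute area in µm² (exterior minus interior rings)."""
    return float(polygon.to_shapely().area)


def _sorted_regions(polygons: list[SubregionAnnotation]) -> list[SubregionAnnotation]:
    rank = {r: i for i, r in enumerate(REGION_PRIORITY)}
    return sorted(polygons, key=lambda p: rank.get(p.region, len(rank)))


def _assign_points(
    xs: np.ndarray, ys: np.ndarray, polygons: list[SubregionAnnotation]
) -> np.ndarray:
    """Region label per point; closed boundaries; priority order on overlap."""
    labels = np.full(len(xs), UNASSIGNED, dtype=object)
    points = shapely.points(xs, ys)
    unset = np.ones(len(xs), dtype=bool)
    for poly in _sorted_regions(polygons):
        if not unset.any():
            break
        geom = poly.to_shapely()
        hit = shapely.covers(geom, points[unset])
        idx = np.flatnonzero(unset)[hit]
        labels[idx] = poly.region
        unset[idx] = False
    return labels


def assign_cells_to_regions(
    cells: pd.DataFrame, polygons: list[SubregionAnnotation]
) -> pd.DataFrame:
    """Label each cell with its containing subregion (``unassigned`` outside).

    Works per sample; polygons whose sample_id does not match a cell's
    sample are ignored for that cell.
    """
    out = cells.copy()
    out["subregion"] = UNASSIGNED
    for sid, idx in cells.groupby("sample_id").groups.items():
        polys = [p for p in polygons if p.sample_id == sid]
        if not polys:
            continue
        out.loc[idx, "subregion"] = _assign_points(
            cells.loc[idx, "x_um"].to_numpy(),
            cells.loc[idx, "y_um"].to_numpy(),
            polys,
        )
    return out


def normalized_region_areas(
    polygons: list[SubregionAnnotation], include_lumen: bool = True
) -> pd.Series:
    """Region -> percentage of total annotated area for one sample."""
    polys = [p for p in polygons if include_lumen or p.region != "lumen"]
    if not polys:
        raise GeometryError("no regions to normalize")
    areas = pd.Series({p.region: polygon_area(p) for p in polys})
    total = areas.sum()
    if total <= 0:
        raise GeometryError("zero total annotated area")
    return 100.0 * areas / total


def region_noise_stats(
    transcripts: pd.DataFrame, polygons: list[SubregionAnnotation]
) -> pd.DataFrame:
    """Per-region transcript and noise accounting for one sample.

    Every transcript (assigned and noise) is binned to a region by its own
    coordinates.  Columns: assigned_transcripts, noise_transcripts,
    noise_ratio = noise/(noise+assigned), noise_share = region noise /
    total sample noise.  A trailing ``unassigned`` row collects transcripts
    outside all polygons, so counts conserve.
    """
    labels = _assign_points(
        transcripts["x_um"].to_numpy(), transcripts["y_um"].to_numpy(), polygons
    )
    noise = is_noise(transcripts)
    regions = [p.region for p in _sorted_regions(polygons)] + [UNASSIGNED]
    rows = []
    total_noise = noise.sum()
    for region in regions:
        m = labels == region
        n_noise = int((m & noise).sum())
        n_assigned = int((m & ~noise).sum())
        denom = n_noise + n_assigned
        rows.append(
            {
                "region": region,
                "assigned_transcripts": n_assigned,
                "noise_transcripts": n_noise,
                "noise_ratio": n_noise / denom if denom else np.nan,
                "noise_share": n_noise / total_noise if total_noise else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("region")


def compare_region_groups(
    values: dict[str, np.ndarray] | pd.Series, groups: pd.Series | None = None
) -> pd.DataFrame:
    """Pairwise two-sided Mann-Whitney-U tests with BH correction.

    ``values`` maps group label -> per-sample statistics (or give a Series
    of values with ``groups`` labels).  All unordered group pairs form the
    BH family.
    """
    if groups is not None:
        values = {g: np.asarray(values[groups == g]) for g in pd.unique(groups)}
    values = {g: np.asarray(v, dtype=float) for g, v in values.items()}
    if len(values) < 2:
        raise ValueError("need at least two groups")
    for g, v in values.items():
        if v.size == 0:
            raise ValueError(f"group {g!r} has no values")
    rows = []
    for a, b in itertools.combinations(values, 2):
        p = mannwhitneyu(values[a], values[b], alternative="two-sided").pvalue
        rows.append({"group_a": a, "group_b": b, "p": float(p)})
    out = pd.DataFrame(rows)
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    return out
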