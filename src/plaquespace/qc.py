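"""Quality control of Baysor-style segmentation output.

Transcript filters (Phred-like Q-score, assignment confidence), cell filters
(non-zero gene count, average assignment confidence, max_cluster_frac
doublet indicator, lifespan stability), area normalization of counts, the
acosh variance-stabilising transform, and the AUC_0.75 criterion used to
pick the best segmentation candidate per sample.

Boundary semantics follow the upstream pipeline's wording: cell-level
removals are strictly "lower than" the threshold, so threshold-equal cells
are KEPT; the transcript confidence filter keeps strictly "> 0.5".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from plaquespace.types import (
    CountTable,
    DataIntegrityError,
    SchemaError,
    is_noise,
)

logger = logging.getLogger(__name__)


@dataclass
class CandidateSegmentation:
    """One segmentation candidate (input combination x scale tag).

    ``scale_um`` and ``scale_std`` are carried as metadata only; selection
    uses the cells' assignment-confidence distribution.
    """

    candidate_id: str
    cells: pd.DataFrame
    counts: CountTable | None = None
    scale_um: float | None = None
    scale_std: str | None = None


def filter_transcripts(
    transcripts: pd.DataFrame, q_min: float = 20.0, conf_min: float = 0.5
) -> pd.DataFrame:
    """Drop low-quality transcripts.

    Keeps transcripts with qscore >= ``q_min``; assigned transcripts must
    additionally have assignment confidence strictly greater than
    ``conf_min``.  Noise transcripts pass the Q filter only and stay flagged
    as noise.
    """
    for col in ("qscore", "cell_id", "assignment_confidence"):
        if col not in transcripts.columns:
            raise SchemaError(f"transcript table missing {col!r}")
    noise = is_noise(transcripts)
    q_ok = transcripts["qscore"].to_numpy() >= q_min
    conf_ok = transcripts["assignment_confidence"].to_numpy() > conf_min
    keep = q_ok & (noise | conf_ok)
    return transcripts.loc[keep].reset_index(drop=True)


def cell_quality_filter(
    cells: pd.DataFrame,
    counts: CountTable,
    min_nonzero_genes: int = 10,
    min_conf: float = 0.75,
    min_max_cluster_frac: float = 0.9,
    min_lifespan: float = 50.0,
) -> tuple[pd.DataFrame, CountTable, dict[str, int]]:
    """Retain cells passing all four segmentation-QC criteria.

    A cell is kept iff its non-zero gene count is >= ``min_nonzero_genes``
    AND confidence >= ``min_conf`` AND max_cluster_frac >=
    ``min_max_cluster_frac`` AND lifespan >= ``min_lifespan``.  Returns the
    retained cells, the matching count subset and per-criterion attrition
    counts (cells failing each criterion; a cell may fail several).
    """
    missing = set(cells["cell_id"]) - set(counts.cell_ids)
    if missing:
        raise DataIntegrityError(
            f"{len(missing)} cells missing from the count table"
        )
    sub = counts.values.loc[cells["cell_id"]]
    nonzero = (sub.to_numpy() > 0).sum(axis=1)
    fail = {
        "nonzero_genes": nonzero < min_nonzero_genes,
        "confidence": cells["avg_assignment_confidence"].to_numpy() < min_conf,
        "max_cluster_frac": cells["max_cluster_frac"].to_numpy() < min_max_cluster_frac,
        "lifespan": cells["lifespan"].to_numpy() < min_lifespan,
    }
    keep = ~np.logical_or.reduce(list(fail.values()))
    attrition = {k: int(v.sum()) for k, v in fail.items()}
    attrition["removed_total"] = int((~keep).sum())
    logger.info("cell QC attrition: %s", attrition)
    kept_cells = cells.loc[keep].reset_index(drop=True)
    kept_counts = CountTable(
        counts.values.loc[kept_cells["cell_id"]], counts.normalized
    )
    return kept_cells, kept_counts, attrition


def area_normalize(counts: CountTable, cells: pd.DataFrame) -> CountTable:
    """Divide each cell's counts by its area in µm²."""
    if counts.normalized:
        raise ValueError("counts are already area-normalized")
    areas = cells.set_index("cell_id")["area_um2"].reindex(counts.cell_ids)
    if areas.isna().any():
        raise DataIntegrityError("count rows without a matching cell")
    if (areas <= 0).any():
        raise ValueError("cell areas must be positive")
    return CountTable(counts.values.div(areas, axis=0), normalized=True)


def acosh_transform(values):
    """Variance-stabilising transform y = acosh(1 + x); y(0) = 0, monotone."""
    arr = np.asarray(values, dtype=float)
    if (arr < 0).any():
        raise ValueError("acosh transform requires nonnegative input")
    return np.arccosh(1.0 + arr)


def confidence_auc(confidences, lower: float = 0.75) -> float:
    """Share of the confidence KDE mass above ``lower`` (AUC_0.75).

    Fits a Gaussian KDE (Scott's rule) to the per-cell average assignment
    confidences, evaluates it on a 512-point grid spanning
    [min - 3h, max + 3h], and returns the integral over [``lower``, 1]
    divided by the total mass on the grid, so candidates are comparable as
    proportions.  Zero-variance input returns 1.0 if the constant is >=
    ``lower`` else 0.0.
    """
    x = np.asarray(confidences, dtype=float)
    if x.size == 0:
        raise ValueError("no confidences given")
    if np.ptp(x) == 0:
        return 1.0 if x[0] >= lower else 0.0
    kde = gaussian_kde(x)  # Scott's rule bandwidth
    h = kde.factor * x.std(ddof=1)
    grid = np.linspace(x.min() - 3 * h, x.max() + 3 * h, 512)
    dens = kde(grid)
    total = np.trapezoid(dens, grid)
    mask = (grid >= lower) & (grid <= 1.0)
    if mask.sum() < 2:
        return 0.0
    upper = np.trapezoid(dens[mask], grid[mask])
    return float(upper / total)


def select_segmentation(candidates: list[CandidateSegmentation]) -> str:
    """Pick the candidate with the highest AUC_0.75; ties by id (logged)."""
    if not candidates:
        raise ValueError("no candidates")
    scored = sorted(
        (
            (-confidence_auc(c.cells["avg_assignment_confidence"]), c.candidate_id)
            for c in candidates
        )
    )
    if len(scored) > 1 and scored[0][0] == scored[1][0]:
        logger.info(
            "AUC tie between %s and %s; choosing lexicographically",
            scored[0][1],
            scored[1][1],
        )
    return scored[0][1]


def noise_fraction(transcripts: pd.DataFrame) -> float:
    """Fraction of transcripts flagged as noise (cell-unassigned)."""
    if len(transcripts) == 0:
        raise ValueError("no transcripts")
    return float(is_noise(transcripts).mean())
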