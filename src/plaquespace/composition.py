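"""Cell-fraction features and morphological clustering of samples.

Per-sample (or per-sample-x-region) substate fraction percentages,
agglomerative Ward clustering of samples on those fractions, OLS and
rank-sum association tests against sample metadata, and the
Benjamini-Hochberg step-up correction used throughout the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def substate_fractions(
    cells: pd.DataFrame,
    stratum: str = "sample",
    exclude_regions: set[str] = frozenset({"thrombus"}),
) -> pd.DataFrame:
    """Fraction matrix: rows = strata, columns = substates, values = %.

    ``stratum`` is ``"sample"`` or ``"sample_region"``.  Cells in
    ``exclude_regions`` (intraluminal thrombi by default) are dropped before
    tallying.  Rows sum to 100; substates absent from a stratum get 0.
    Empty strata (all cells excluded) are dropped with a warning.
    """
    kept = cells
    if exclude_regions and "subregion" in cells.columns:
        kept = cells[~cells["subregion"].isin(exclude_regions)]
    if stratum == "sample":
        keys = kept["sample_id"]
    elif stratum == "sample_region":
        if "subregion" not in kept.columns:
            raise ValueError("sample_region stratification needs a subregion column")
        keys = kept["sample_id"] + "/" + kept["subregion"]
    else:
        raise ValueError(f"unknown stratum {stratum!r}")
    counts = pd.crosstab(keys, kept["substate"])
    dropped = set(pd.unique(cells["sample_id"])) - set(
        k.split("/")[0] for k in counts.index
    )
    if dropped:
        logger.warning("strata with no kept cells dropped: %s", sorted(dropped))
    frac = 100.0 * counts.div(counts.sum(axis=1), axis=0)
    frac.index.name = stratum
    frac.columns.name = "substate"
    return frac


@dataclass
class MorphologyClustering:
    """Ward merge tree plus flat labels at the chosen cut."""

    linkage: np.ndarray
    k: int
    labels: pd.Series  # sample -> cluster id (1..k)


def ward_cluster(features: pd.DataFrame, k: int) -> MorphologyClustering:
    """Agglomerative Ward clustering on Euclidean distances, cut at k."""
    if k > len(features):
        raise ValueError("k exceeds the number of rows")
    if features.isna().any().any():
        raise ValueError("features contain missing values")
    Z = sch.linkage(features.to_numpy(), method="ward")
    labels = sch.fcluster(Z, t=k, criterion="maxclust")
    return MorphologyClustering(Z, k, pd.Series(labels, index=features.index))


def associate_numeric(pairs: list[tuple[str, np.ndarray, np.ndarray]]) -> pd.DataFrame:
    """OLS association per (name, x, y) pair; BH across the family.

    Reports slope, R² and the two-sided t-test p-value of the slope.  This
    is the plain fixed-effects fallback; repeated measures per patient are
    not modelled.
    """
    rows = []
    for name, x, y in pairs:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.size < 3 or x.size != y.size:
            raise ValueError(f"{name}: need >=3 paired values")
        if np.ptp(x) == 0:
            raise ValueError(f"{name}: zero variance in x")
        fit = stats.linregress(x, y)
        rows.append(
            {
                "name": name,
                "slope": fit.slope,
                "r_squared": fit.rvalue**2,
                "p": float(fit.pvalue),
            }
        )
    out = pd.DataFrame(rows)
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    return out


def associate_categorical(
    pairs: list[tuple[str, np.ndarray, np.ndarray]]
) -> pd.DataFrame:
    """Two-sided rank-sum test per (name, values, group labels); BH family.

    Groups must be a 2-level factor.  Exact p-values for small tie-free
    samples, normal approximation with tie correction otherwise (scipy's
    automatic policy).
    """
    rows = []
    for name, values, groups in pairs:
        values = np.asarray(values, dtype=float)
        groups = np.asarray(groups)
        levels = pd.unique(groups)
        if len(levels) != 2:
            raise ValueError(f"{name}: groups must have exactly two levels")
        a = values[groups == levels[0]]
        b = values[groups == levels[1]]
        if a.size == 0 or b.size == 0:
            raise ValueError(f"{name}: empty group")
        p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        rows.append({"name": name, "p": float(p)})
    out = pd.DataFrame(rows)
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    return out
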