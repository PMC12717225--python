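"""Shared containers and error types.

Cells and transcripts travel through the pipeline as plain pandas DataFrames
with a documented column contract (see below); the thin dataclasses here wrap
the pieces that need extra state: a count matrix that remembers whether it
has been area-normalized, a subregion polygon that may carry interior rings
(annular regions), and a generated sample bundling all of it with its planted
ground truth.

Cell table columns
    cell_id, sample_id, x_um, y_um, area_um2, substate,
    avg_assignment_confidence, max_cluster_frac, lifespan
    (optional: low_level_type, subregion)

Transcript table columns
    gene, x_um, y_um, qscore, cell_id (NaN for noise), assignment_confidence
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for transcripts not assigned to any cell.  Stored as NaN in the
#: ``cell_id`` column; :func:`is_noise` is the one canonical test.
NOISE = None

REGION_PRIORITY = (
    "lumen",
    "thrombus",
    "necrotic_core",
    "fibrous_cap",
    "intima",
    "media",
)

CELL_COLUMNS = [
    "cell_id",
    "sample_id",
    "x_um",
    "y_um",
    "area_um2",
    "substate",
    "avg_assignment_confidence",
    "max_cluster_frac",
    "lifespan",
]

TRANSCRIPT_COLUMNS = [
    "gene",
    "x_um",
    "y_um",
    "qscore",
    "cell_id",
    "assignment_confidence",
]


class ConfigError(ValueError):
    """Inconsistent simulation or analysis configuration."""


class SchemaError(ValueError):
    """An input table is missing required fields."""


class GeometryError(ValueError):
    """A polygon is degenerate or self-intersecting."""


class DataIntegrityError(ValueError):
    """Cross-references between tables are broken."""


def is_noise(transcripts: pd.DataFrame) -> np.ndarray:
    """Boolean mask of noise (cell-unassigned) transcripts."""
    return transcripts["cell_id"].isna().to_numpy()


@dataclass
class CountTable:
    """Cells x genes count matrix with a normalization flag.

    ``values`` is a DataFrame indexed by cell id with gene-name columns.
    ``normalized`` records whether entries are raw transcript counts or
    counts divided by cell area (µm²).
    """

    values: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("count table contains negative entries")

    @property
    def cell_ids(self) -> pd.Index:
        return self.values.index

    @property
    def genes(self) -> pd.Index:
        return self.values.columns

    def copy(self) -> "CountTable":
        return CountTable(self.values.copy(), self.normalized)


@dataclass
class SubregionAnnotation:
    """One named subregion polygon of one sample, coordinates in µm.

    ``exterior`` is an (n, 3<=n) array of ring vertices (first vertex not
    repeated); ``holes`` holds interior rings, used for annular regions such
    as the media.  Rings must each be simple; validity is checked through
    shapely when the polygon is materialised.
    """

    sample_id: str
    region: str
    exterior: np.ndarray
    holes: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exterior = np.asarray(self.exterior, dtype=float)
        if self.exterior.ndim != 2 or self.exterior.shape[1] != 2:
            raise GeometryError("polygon vertices must be an (n, 2) array")
        if len(self.exterior) < 3:
            raise GeometryError("polygon needs at least 3 vertices")
        self.holes = [np.asarray(h, dtype=float) for h in self.holes]
        for h in self.holes:
            if len(h) < 3:
                raise GeometryError("interior ring needs at least 3 vertices")

    def to_shapely(self):
        from shapely.geometry import Polygon

        poly = Polygon(self.exterior, [h for h in self.holes])
        if not poly.is_valid:
            raise GeometryError(
                f"invalid polygon for region {self.region!r} "
                f"of sample {self.sample_id!r}"
            )
        return poly


@dataclass
class SyntheticSample:
    """A generated tissue sample plus its planted ground truth."""

    sample_id: str
    condition: str
    cells: pd.DataFrame
    transcripts: pd.DataFrame
    counts: CountTable
    polygons: list[SubregionAnnotation]
    truth: pd.DataFrame
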