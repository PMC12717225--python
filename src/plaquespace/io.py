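"""Readers and writers for the Baysor-style on-disk layout.

cells.csv / transcripts.csv, counts in MatrixMarket with row/col sidecars,
subregion polygons as a GeoJSON FeatureCollection, metadata.csv.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from plaquespace.types import (
    CountTable,
    SchemaError,
    SubregionAnnotation,
    SyntheticSample,
    CELL_COLUMNS,
    TRANSCRIPT_COLUMNS,
)


def write_cells(cells: pd.DataFrame, path: str | Path) -> None:
    cells.to_csv(path, index=False)


def read_cells(path: str | Path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a cell-stats CSV; ``column_map`` renames dialect columns."""
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in CELL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cell table missing columns: {missing}")
    return df


def write_transcripts(transcripts: pd.DataFrame, path: str | Path) -> None:
    transcripts.to_csv(path, index=False)


def read_transcripts(path: str | Path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in TRANSCRIPT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"transcript table missing columns: {missing}")
    return df


def write_counts(counts: CountTable, prefix: str | Path) -> None:
    """Write ``<prefix>.mtx`` plus ``<prefix>.rows.txt`` / ``.cols.txt``."""
    prefix = Path(prefix)
    mat = scipy.sparse.csr_matrix(counts.values.to_numpy())
    scipy.io.mmwrite(str(prefix.with_suffix(".mtx")), mat)
    prefix.with_suffix(".rows.txt").write_text("\n".join(map(str, counts.cell_ids)) + "\n")
    prefix.with_suffix(".cols.txt").write_text("\n".join(map(str, counts.genes)) + "\n")


def read_counts(prefix: str | Path, normalized: bool = False) -> CountTable:
    prefix = Path(prefix)
    mat = scipy.io.mmread(str(prefix.with_suffix(".mtx"))).toarray()
    rows = prefix.with_suffix(".rows.txt").read_text().splitlines()
    cols = prefix.with_suffix(".cols.txt").read_text().splitlines()
    df = pd.DataFrame(mat, index=pd.Index(rows, name="cell_id"), columns=cols)
    return CountTable(df, normalized=normalized)


def _ring_coords(ring: np.ndarray) -> list[list[float]]:
    closed = np.vstack([ring, ring[:1]])
    return [[float(x), float(y)] for x, y in closed]


def write_polygons(polygons: list[SubregionAnnotation], path: str | Path) -> None:
    """GeoJSON FeatureCollection; coordinates in µm, one Feature per region."""
    features = []
    for p in polygons:
        coords = [_ring_coords(p.exterior)] + [_ring_coords(h) for h in p.holes]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": coords},
                "properties": {"sample_id": p.sample_id, "region": p.region},
            }
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )


def read_polygons(path: str | Path) -> list[SubregionAnnotation]:
    data = json.loads(Path(path).read_text())
    out = []
    for feat in data["features"]:
        rings = feat["geometry"]["coordinates"]
        exterior = np.asarray(rings[0][:-1], dtype=float)
        holes = [np.asarray(r[:-1], dtype=float) for r in rings[1:]]
        props = feat["properties"]
        out.append(
            SubregionAnnotation(props["sample_id"], props["region"], exterior, holes)
        )
    return out


def write_sample(sample: SyntheticSample, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_cells(sample.cells, out / "cells.csv")
    write_transcripts(sample.transcripts, out / "transcripts.csv")
    write_counts(sample.counts, out / "counts")
    write_polygons(sample.polygons, out / "polygons.geojson")
    sample.truth.to_csv(out / "truth.csv", index=False)


def write_cohort(samples, metadata: pd.DataFrame, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    metadata.to_csv(out / "metadata.csv", index=False)
    for s in samples:
        write_sample(s, out / s.sample_id)
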