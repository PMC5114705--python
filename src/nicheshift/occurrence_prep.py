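"""Occurrence record cleaning and spatial thinning.

Presence records arrive as CSV tables (``species,lon,lat,source_id``).
Cleaning removes malformed, out-of-extent, nodata-cell and duplicate rows;
thinning keeps at most one record per analysis-grid cell to reduce the
footprint of spatially clustered sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .raster_stack import GridSpec, RasterStack

__all__ = ["OccurrenceSet", "read_occurrences", "write_occurrences", "clean_records", "thin_to_grid"]

_COLUMNS = ["species", "lon", "lat", "source_id"]


@dataclass
class OccurrenceSet:
    """Cleaned (and possibly thinned) presence records for one species."""

    species: str
    records: pd.DataFrame  # columns: species, lon, lat, source_id
    n_raw: int = 0
    n_after_clean: int = 0
    n_after_thin: int | None = None
    removal_report: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["reason", "n_removed"])
    )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.records["lon"], self.records["lat"]))


def read_occurrences(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"occurrence CSV missing columns: {missing}")
    return df[_COLUMNS].copy()


def write_occurrences(occ: OccurrenceSet, path: str | Path) -> None:
    occ.records[_COLUMNS].to_csv(path, index=False)


def clean_records(records: pd.DataFrame, stack: RasterStack, species: str | None = None) -> OccurrenceSet:
    """Drop invalid, duplicated, out-of-extent and masked-cell records.

    Removal reasons are tallied per category; an empty input yields an empty
    set with zeroed counts rather than an error.
    """
    df = records.copy().reset_index(drop=True)
    if species is not None:
        df = df[df["species"] == species].reset_index(drop=True)
    elif len(df) > 0:
        species = str(df["species"].iloc[0])
    else:
        species = ""
    n_raw = len(df)
    reasons: dict[str, int] = {}

    lon = pd.to_numeric(df["lon"], errors="coerce")
    lat = pd.to_numeric(df["lat"], errors="coerce")
    valid = (
        np.isfinite(lon)
        & np.isfinite(lat)
        & (lon >= -180.0)
        & (lon <= 180.0)
        & (lat >= -90.0)
        & (lat <= 90.0)
    )
    reasons["invalid_coordinates"] = int((~valid).sum())
    df = df[valid.to_numpy()].reset_index(drop=True)
    df["lon"] = df["lon"].astype(float)
    df["lat"] = df["lat"].astype(float)

    dup = df.duplicated(subset=["species", "lon", "lat"], keep="first")
    reasons["duplicate"] = int(dup.sum())
    df = df[~dup.to_numpy()].reset_index(drop=True)

    if len(df) > 0:
        _, _, _, outside, masked = _locate(df, stack)
        reasons["outside_extent"] = int(outside.sum())
        reasons["masked_cell"] = int(masked.sum())
        df = df[~(outside | masked)].reset_index(drop=True)
    else:
        reasons["outside_extent"] = 0
        reasons["masked_cell"] = 0

    report = pd.DataFrame(
        {"reason": list(reasons), "n_removed": [reasons[k] for k in reasons]}
    )
    return OccurrenceSet(
        species=species,
        records=df,
        n_raw=n_raw,
        n_after_clean=len(df),
        removal_report=report,
    )


def _locate(df: pd.DataFrame, stack: RasterStack):
    from .raster_stack import extract_values

    values, rows, cols, outside, masked = extract_values(
        stack, list(zip(df["lon"], df["lat"]))
    )
    return values, rows, cols, outside, masked


def thin_to_grid(
    occ: OccurrenceSet,
    grid: GridSpec,
    seed: int | None = None,
    rule: str = "first_source",
) -> OccurrenceSet:
    """Keep at most one record per grid cell.

    ``rule='first_source'`` (default) keeps, within each cell, the record
    that sorts first by ``(source_id, lon, lat)`` — fully deterministic.
    ``rule='random'`` draws one record per cell with a seeded generator.
    Output is sorted by (row, col); thinning is idempotent.
    """
    df = occ.records.copy().reset_index(drop=True)
    if len(df) == 0:
        out = OccurrenceSet(occ.species, df, occ.n_raw, occ.n_after_clean, 0, occ.removal_report)
        return out
    rc = [grid.rowcol(lon, lat) for lon, lat in zip(df["lon"], df["lat"])]
    df["_row"] = [r for r, _ in rc]
    df["_col"] = [c for _, c in rc]
    if (df["_row"] < 0).any():
        raise ValueError("records outside the thinning grid; clean first")

    if rule == "first_source":
        df = df.sort_values(["_row", "_col", "source_id", "lon", "lat"], kind="mergesort")
        kept = df.drop_duplicates(subset=["_row", "_col"], keep="first")
    elif rule == "random":
        rng = np.random.default_rng(seed)
        picks = []
        for _, group in df.sort_values(["_row", "_col", "source_id"], kind="mergesort").groupby(
            ["_row", "_col"], sort=True
        ):
            picks.append(group.index[rng.integers(len(group))])
        kept = df.loc[picks]
    else:
        raise ValueError(f"unknown thinning rule {rule!r}")

    kept = kept.sort_values(["_row", "_col"], kind="mergesort").drop(columns=["_row", "_col"])
    kept = kept.reset_index(drop=True)
    return OccurrenceSet(
        species=occ.species,
        records=kept,
        n_raw=occ.n_raw,
        n_after_clean=occ.n_after_clean,
        n_after_thin=len(kept),
        removal_report=occ.removal_report,
    )
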