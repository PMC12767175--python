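"""Occurrence records: reading, validation, and spatial thinning to one per cell."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .rasters import GridGeometry

__all__ = ["OccurrenceSet", "OccurrenceFormatError", "read_occurrences",
           "thin_to_grid", "write_occurrences"]

log = logging.getLogger(__name__)

RECORD_COLUMNS = ["lon", "lat", "date", "record_id"]


class OccurrenceFormatError(ValueError):
    """Occurrence CSV is missing a required column."""


@dataclass
class OccurrenceSet:
    """Point records for one species.

    ``records`` has columns lon, lat, date (nullable datetime), record_id.
    """

    species_id: str
    records: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=RECORD_COLUMNS))

    def __post_init__(self):
        df = self.records
        missing = set(RECORD_COLUMNS) - set(df.columns)
        if missing:
            raise OccurrenceFormatError(f"records missing columns {sorted(missing)}")
        self.records = df[RECORD_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def coords(self) -> np.ndarray:
        return self.records[["lon", "lat"]].to_numpy(dtype=float)


def read_occurrences(path) -> dict[str, OccurrenceSet]:
    """Read a species,lon,lat[,date[,record_id]] CSV into per-species sets.

    Rows with missing or non-finite coordinates are dropped (and counted in the
    log); exact (species, lon, lat) duplicates collapse to one record.
    """
    df = pd.read_csv(path, dtype={"species": str})
    for col in ("species", "lon", "lat"):
        if col not in df.columns:
            raise OccurrenceFormatError(f"{path}: missing required column {col!r}")
    n_in = len(df)
    df["lon"] = pd.to_numeric(df["lon"], errors="coerce")
    df["lat"] = pd.to_numeric(df["lat"], errors="coerce")
    ok = np.isfinite(df["lon"]) & np.isfinite(df["lat"]) & df["species"].notna()
    n_bad = int((~ok).sum())
    df = df[ok]
    df = df.drop_duplicates(subset=["species", "lon", "lat"], keep="first")
    n_dup = n_in - n_bad - len(df)
    if n_bad or n_dup:
        log.info("%s: dropped %d invalid-coordinate rows, %d duplicates", path, n_bad, n_dup)
    if "date" in df.columns:
        df["date"] = pd.to_datetime(df["date"], errors="coerce")
    else:
        df["date"] = pd.NaT
    if "record_id" not in df.columns:
        df = df.copy()
        df["record_id"] = [f"r{i:06d}" for i in df.index]
    out: dict[str, OccurrenceSet] = {}
    for sp, grp in df.groupby("species", sort=True):
        out[sp] = OccurrenceSet(sp, grp[RECORD_COLUMNS].reset_index(drop=True))
    return out


def thin_to_grid(occ: OccurrenceSet, geom: GridGeometry) -> OccurrenceSet:
    """Spatial thinning: keep exactly one record per occupied grid cell.

    The kept record is the earliest-dated one (records without a date sort
    after any dated record); ties break on the lexicographically smallest
    record_id, so the result does not depend on input row order.  Records
    outside the grid are dropped with a log message, not an error.
    """
    df = occ.records
    if df.empty:
        return OccurrenceSet(occ.species_id, df.copy())
    row, col = geom.cell_index(df["lon"].to_numpy(), df["lat"].to_numpy())
    inside = row >= 0
    n_out = int((~inside).sum())
    if n_out:
        log.info("%s: dropped %d records outside the grid", occ.species_id, n_out)
    df = df[inside].copy()
    if df.empty:
        return OccurrenceSet(occ.species_id, df)
    df["_cell"] = row[inside] * geom.n_cols + col[inside]
    # NaT must sort last so undated records lose to dated ones
    df["_datekey"] = df["date"].fillna(pd.Timestamp.max)
    df = df.sort_values(["_cell", "_datekey", "record_id"], kind="mergesort")
    kept = df.groupby("_cell", sort=True).head(1)
    kept = kept.sort_values("record_id", kind="mergesort")
    return OccurrenceSet(occ.species_id, kept[RECORD_COLUMNS].reset_index(drop=True))


def write_occurrences(sets: dict[str, OccurrenceSet], path) -> None:
    """Write per-species sets back to one species,lon,lat,date,record_id CSV."""
    frames = []
    for sp in sorted(sets):
        df = sets[sp].records.copy()
        df.insert(0, "species", sp)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["species", *RECORD_COLUMNS])
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False)
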