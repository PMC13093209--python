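"""Occurrence reading, cleaning, and one-record-per-cell spatial thinning.

Presence records arrive as longitude/latitude points (WGS84 decimal
degrees) compiled from heterogeneous sources; they are deduplicated,
screened for sentinel coordinates, and thinned so that at most one record
remains per grid cell — the standard defence against spatial
autocorrelation when occurrences are denser than the predictor grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import GridSpec

COLUMNS = ["id", "lon", "lat", "source"]


def _append_rejects(rejects: pd.DataFrame, removed: pd.DataFrame) -> pd.DataFrame:
    frames = [f for f in (rejects, removed) if len(f)]
    if not frames:
        return rejects
    return pd.concat(frames, ignore_index=True)


@dataclass
class OccurrenceSet:
    """Ordered occurrence records, optionally tied to a thinning grid.

    ``frame`` has columns id, lon, lat, source (row order meaningful:
    within-cell thinning keeps the first record). ``rejects`` accumulates
    rows removed with a stated reason rather than silently dropping them.
    """

    frame: pd.DataFrame
    grid: GridSpec | None = None
    rejects: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=COLUMNS + ["reason"])
    )
    log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"occurrence frame missing columns {missing}")
        self.frame = self.frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def coords(self) -> np.ndarray:
        return self.frame[["lon", "lat"]].to_numpy(dtype=float)


def read_occurrences(
    path,
    lon_col: str = "lon",
    lat_col: str = "lat",
    id_col: str | None = "id",
    source_col: str | None = "source",
) -> OccurrenceSet:
    """Read a CSV of point records, routing malformed rows to the rejects.

    Rows with unparseable or out-of-range coordinates (|lat| > 90,
    |lon| > 180, non-finite) are kept in ``rejects`` with a reason; row
    order of valid records is preserved.
    """
    raw = pd.read_csv(path)
    for col, label in ((lon_col, "longitude"), (lat_col, "latitude")):
        if col not in raw.columns:
            raise ValueError(
                f"missing {label} column {col!r}; available: {list(raw.columns)}"
            )
    frame = pd.DataFrame(
        {
            "id": raw[id_col].astype(str)
            if id_col and id_col in raw.columns
            else [f"rec{i}" for i in range(len(raw))],
            "lon": pd.to_numeric(raw[lon_col], errors="coerce"),
            "lat": pd.to_numeric(raw[lat_col], errors="coerce"),
            "source": raw[source_col].astype(str)
            if source_col and source_col in raw.columns
            else "",
        }
    )
    reasons = pd.Series("", index=frame.index)
    bad_num = ~np.isfinite(frame["lon"]) | ~np.isfinite(frame["lat"])
    reasons[bad_num] = "non-numeric coordinate"
    lat_oob = np.isfinite(frame["lat"]) & (frame["lat"].abs() > 90)
    reasons[lat_oob] = "latitude out of range"
    lon_oob = np.isfinite(frame["lon"]) & (frame["lon"].abs() > 180)
    reasons[lon_oob] = "longitude out of range"
    bad = reasons != ""
    rejects = frame[bad].assign(reason=reasons[bad])
    return OccurrenceSet(
        frame=frame[~bad],
        rejects=rejects.reset_index(drop=True),
        log={"read": len(frame), "rejected_on_read": int(bad.sum())},
    )


def clean_occurrences(occ: OccurrenceSet) -> OccurrenceSet:
    """Collapse duplicate coordinates and drop sentinel (0, 0) records.

    Coordinates are rounded to 6 decimal places (~0.1 m) before duplicate
    detection; the first record of each duplicate group is kept. Records at
    exactly (0, 0) — a classic data-entry sentinel — are removed.
    Idempotent.
    """
    frame = occ.frame.copy()
    rounded = frame[["lon", "lat"]].round(6)
    at_zero = (rounded["lon"] == 0.0) & (rounded["lat"] == 0.0)
    dup = rounded.duplicated(keep="first") & ~at_zero
    removed = frame[at_zero | dup].assign(
        reason=np.where(at_zero[at_zero | dup], "sentinel (0,0) coordinate", "duplicate coordinate")
    )
    kept = frame[~(at_zero | dup)]
    log = dict(occ.log)
    log.update(
        {"duplicates_removed": int(dup.sum()), "zero_coordinate_removed": int(at_zero.sum())}
    )
    return OccurrenceSet(
        frame=kept,
        grid=occ.grid,
        rejects=_append_rejects(occ.rejects, removed),
        log=log,
    )


def thin_to_grid(occ: OccurrenceSet, grid: GridSpec) -> OccurrenceSet:
    """Retain at most one record per grid cell (first in input order).

    Records outside the grid extent go to the rejects with a reason. The
    result carries the grid reference; re-thinning with the same grid is a
    no-op.
    """
    frame = occ.frame.copy()
    row, col = grid.cell_index(frame["lon"].to_numpy(), frame["lat"].to_numpy())
    outside = row < 0
    cell = row.astype(np.int64) * grid.n_cols + col
    dup_cell = pd.Series(cell).duplicated(keep="first").to_numpy() & ~outside
    removed = frame[outside | dup_cell].assign(
        reason=np.where(outside[outside | dup_cell], "outside grid extent", "cell already occupied")
    )
    kept = frame[~(outside | dup_cell)].copy()
    kept["grid_row"] = row[~(outside | dup_cell)]
    kept["grid_col"] = col[~(outside | dup_cell)]
    log = dict(occ.log)
    log.update(
        {"outside_grid": int(outside.sum()), "thinned_within_cell": int(dup_cell.sum())}
    )
    return OccurrenceSet(
        frame=kept,
        grid=grid,
        rejects=_append_rejects(occ.rejects, removed),
        log=log,
    )
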