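"""Occurrence records: container, cleaning, thinning, and modelability.

The cleaning chain mirrors standard presence-only hygiene for herpetofauna
databases: drop records implausibly far from the species' expert range map
(400 km buffer), drop records at known problem coordinates (capitals, museums,
institute gardens) and exact duplicates, thin to one record per 1 km grid
cell, and finally require at least five records for a species to be modelled.
Filter order is fixed (buffer -> blacklist/dedup -> thinning -> minimum
records) because the order changes the counts.

Every record keeps a provenance flag: it is either kept, or removed with
exactly one reason.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import cKDTree
from shapely.geometry.base import BaseGeometry

from .grid import GridSpec

logger = logging.getLogger(__name__)

#: admissible removal reasons (outside_grid only arises for malformed inputs
#: that fall off the analysis grid entirely)
REMOVAL_REASONS = frozenset(
    {"outside_range_buffer", "blacklisted", "duplicate", "thinned", "outside_grid"}
)

RECORD_COLUMNS = ["x_km", "y_km", "year", "source", "kept", "removal_reason"]


@dataclass
class OccurrenceSet:
    """Point records for one species with per-record provenance."""

    species_id: str
    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records
        if "kept" not in df.columns:
            df = df.assign(kept=True, removal_reason="")
        for col in ("year", "source"):
            if col not in df.columns:
                df[col] = 0 if col == "year" else "unknown"
        self.records = df[RECORD_COLUMNS].reset_index(drop=True)
        xy = self.records[["x_km", "y_km"]].to_numpy(float)
        if xy.size and not np.all(np.isfinite(xy)):
            raise ValueError(f"{self.species_id}: non-finite coordinates")
        bad = set(self.records.loc[~self.records["kept"], "removal_reason"]) - REMOVAL_REASONS
        if bad:
            raise ValueError(f"unknown removal reasons: {bad}")

    @classmethod
    def from_points(cls, species_id: str, x, y, year=None, source="synthetic") -> "OccurrenceSet":
        x = np.atleast_1d(np.asarray(x, float))
        y = np.atleast_1d(np.asarray(y, float))
        n = x.size
        df = pd.DataFrame(
            {
                "x_km": x,
                "y_km": y,
                "year": np.full(n, 0) if year is None else np.atleast_1d(year),
                "source": source,
            }
        )
        return cls(species_id, df)

    @property
    def kept(self) -> pd.DataFrame:
        return self.records[self.records["kept"]]

    @property
    def n_kept(self) -> int:
        return int(self.records["kept"].sum())

    def kept_xy(self) -> np.ndarray:
        return self.kept[["x_km", "y_km"]].to_numpy(float)

    def _removed(self, idx: np.ndarray, reason: str) -> "OccurrenceSet":
        df = self.records.copy()
        df.loc[idx, "kept"] = False
        df.loc[idx, "removal_reason"] = reason
        return OccurrenceSet(self.species_id, df)


@dataclass
class RangePolygon:
    """Expert range map for one species as planar polygons in km units."""

    species_id: str
    polygons: BaseGeometry

    def __post_init__(self) -> None:
        if not self.polygons.is_valid:
            raise ValueError(f"{self.species_id}: invalid (self-intersecting) polygon")


def filter_by_range_buffer(
    occ: OccurrenceSet, range_poly: RangePolygon | None, buffer_km: float = 400.0
) -> OccurrenceSet:
    """Remove kept records farther than ``buffer_km`` from the range polygon.

    Distance is planar point-to-polygon distance; points on or inside the
    polygon have distance 0.  A record exactly at ``buffer_km`` is kept
    (removal requires strictly exceeding the buffer).  With no polygon
    available all records are kept and a warning is logged.
    """
    if buffer_km < 0:
        raise ValueError("buffer_km must be non-negative")
    if range_poly is None:
        logger.warning("%s: no range polygon; buffer filter skipped", occ.species_id)
        return OccurrenceSet(occ.species_id, occ.records.copy())
    kept = occ.records["kept"].to_numpy()
    pts = shapely.points(occ.records.loc[kept, ["x_km", "y_km"]].to_numpy(float))
    dist = shapely.distance(pts, range_poly.polygons)
    idx = occ.records.index[kept][dist > buffer_km]
    return occ._removed(idx, "outside_range_buffer")


def clean_coordinates(
    occ: OccurrenceSet,
    blacklist: np.ndarray | None = None,
    radius_km: float = 1.0,
    dedup: bool = True,
) -> OccurrenceSet:
    """Remove records near blacklisted points and (optionally) exact duplicates."""
    if radius_km < 0:
        raise ValueError("radius_km must be non-negative")
    out = occ
    if blacklist is not None and len(blacklist):
        tree = cKDTree(np.asarray(blacklist, float))
        kept = out.records["kept"].to_numpy()
        xy = out.records.loc[kept, ["x_km", "y_km"]].to_numpy(float)
        d, _ = tree.query(xy)
        idx = out.records.index[kept][d <= radius_km]
        out = out._removed(idx, "blacklisted")
    if dedup:
        kept_df = out.records[out.records["kept"]]
        dup = kept_df.duplicated(subset=["x_km", "y_km"], keep="first")
        out = out._removed(kept_df.index[dup], "duplicate")
    return out


def filter_by_year(
    occ: OccurrenceSet, min_year: int | None = None, max_year: int | None = None
) -> OccurrenceSet:
    """Optional temporal filter (off by default; synthetic data has no real years)."""
    if min_year is None and max_year is None:
        return occ
    kept = occ.records["kept"]
    years = occ.records["year"]
    bad = kept & (
        (years < (min_year if min_year is not None else -np.inf))
        | (years > (max_year if max_year is not None else np.inf))
    )
    # out-of-window records are treated like blacklisted provenance problems
    return occ._removed(occ.records.index[bad], "blacklisted")


def thin_occurrences(occ: OccurrenceSet, grid: GridSpec) -> OccurrenceSet:
    """Thin to one record per occupied grid cell (first record in input order).

    Records outside the grid extent are flagged removed with a warning.
    """
    kept = occ.records["kept"].to_numpy()
    xy = occ.records.loc[kept, ["x_km", "y_km"]].to_numpy(float)
    row, col = grid.cell_of(xy[:, 0], xy[:, 1])
    inside = grid.contains(row, col)
    out = occ
    if not inside.all():
        logger.warning(
            "%s: %d record(s) outside grid extent removed", occ.species_id, int((~inside).sum())
        )
        out = out._removed(occ.records.index[kept][~inside], "outside_grid")
    kept_idx = occ.records.index[kept][inside]
    cells = pd.Series(row[inside] * grid.n_cols + col[inside], index=kept_idx)
    dup = cells.duplicated(keep="first")
    return out._removed(kept_idx[dup], "thinned")


def occupied_cells(occ: OccurrenceSet, grid: GridSpec) -> np.ndarray:
    """Boolean raster of cells holding at least one kept record."""
    mask = np.zeros(grid.shape, dtype=bool)
    xy = occ.kept_xy()
    if xy.size:
        row, col = grid.cell_of(xy[:, 0], xy[:, 1])
        ok = grid.contains(row, col)
        mask[row[ok], col[ok]] = True
    return mask


def select_modelable_species(
    occ_sets: dict[str, OccurrenceSet] | list[OccurrenceSet], min_records: int = 5
) -> list[str]:
    """Species with at least ``min_records`` kept (thinned) records."""
    sets = occ_sets.values() if isinstance(occ_sets, dict) else occ_sets
    return [o.species_id for o in sets if o.n_kept >= min_records]


def cleaning_report(
    stages: dict[str, dict[str, OccurrenceSet]], min_records: int = 5
) -> pd.DataFrame:
    """Per-species record counts at each cleaning stage.

    ``stages`` maps stage name (``input``, ``buffer``, ``clean``, ``thin``)
    to a dict of species_id -> OccurrenceSet after that stage.
    """
    rows = []
    for sp in stages["input"]:
        n_thin = stages["thin"][sp].n_kept
        rows.append(
            {
                "species_id": sp,
                "n_input": len(stages["input"][sp].records),
                "n_after_buffer": stages["buffer"][sp].n_kept,
                "n_after_clean": stages["clean"][sp].n_kept,
                "n_after_thin": n_thin,
                "modelable": n_thin >= min_records,
            }
        )
    return pd.DataFrame(rows)
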