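"""Cell-level richness/loss maps, priority areas, and conservation gaps.

Conservation priority areas are cells in the top 20% of current species
richness and the bottom 20% of projected species loss (climate-robust,
species-rich cells); gaps are priority cells outside the PA network.
Bivariate decile classification uses the inverse empirical CDF (type-1)
quantile so bin boundaries are bit-exact across platforms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ensemble import BinaryRange
from .grid import GridSpec
from .landscape import PAMask, PartitionRasters

logger = logging.getLogger(__name__)


def richness_map(ranges: dict[str, BinaryRange], grid: GridSpec) -> np.ndarray:
    """Per-cell count of species whose range includes the cell."""
    rich = np.zeros(grid.shape, dtype=np.int32)
    for r in ranges.values():
        if r.mask.shape != grid.shape:
            raise ValueError(f"{r.species_id}: range not on the shared grid")
        rich += r.mask
    return rich


def species_loss_map(
    current: dict[str, BinaryRange], future: dict[str, BinaryRange], grid: GridSpec
) -> np.ndarray:
    """Per-cell percent of current species lost by the future scenario.

    Cells with zero current richness are masked (NaN) and excluded from any
    downstream quantile computation.
    """
    rc = richness_map(current, grid).astype(float)
    rf = richness_map(future, grid).astype(float)
    if np.any(rf > rc):
        raise ValueError("future richness exceeds current richness (containment broken)")
    with np.errstate(divide="ignore", invalid="ignore"):
        loss = 100.0 * (rc - rf) / rc
    loss[rc == 0] = np.nan
    return loss


def quantile_classify(values: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Classify valid cells into quantile bins 1..n_bins (0 = invalid).

    Bin k holds values in ``(q_{(k-1)/n}, q_{k/n}]`` with type-1
    (inverse-empirical-CDF) quantiles; tied values fall into the lowest
    admissible bin, so the map is monotone in the cell value.
    """
    values = np.asarray(values, float)
    valid = np.isfinite(values)
    v = values[valid]
    if v.size < n_bins:
        raise ValueError(f"need at least {n_bins} valid cells")
    if np.ptp(v) == 0:
        logger.warning("all values identical; single quantile bin")
        out = np.zeros(values.shape, dtype=np.int16)
        out[valid] = 1
        return out
    qs = np.quantile(v, np.arange(1, n_bins) / n_bins, method="inverted_cdf")
    out = np.zeros(values.shape, dtype=np.int16)
    out[valid] = 1 + np.searchsorted(qs, v, side="left")
    return out


@dataclass
class PriorityMap:
    """Bivariate decile classification plus priority and gap masks."""

    grid: GridSpec
    richness_bin: np.ndarray
    loss_bin: np.ndarray
    priority: np.ndarray
    gap: np.ndarray


def identify_priority_and_gaps(
    richness: np.ndarray,
    loss: np.ndarray,
    pa: PAMask,
    subset: str = "strict",
    top_frac: float = 0.2,
    bottom_frac: float = 0.2,
    n_bins: int = 10,
) -> PriorityMap:
    """Top-richness / bottom-loss priority cells and their unprotected subset.

    Valid cells are those with a defined loss value (current richness > 0).
    Priority: richness >= the (1 - top_frac) quantile AND loss <= the
    bottom_frac quantile of the valid-cell distributions (boundaries
    inclusive).  Gap: priority AND not protected.
    """
    richness = np.asarray(richness, float)
    loss = np.asarray(loss, float)
    if richness.shape != loss.shape or richness.shape != pa.grid.shape:
        raise ValueError("rasters must be co-registered")
    valid = np.isfinite(loss) & np.isfinite(richness)
    if not valid.any():
        raise ValueError("no valid cells")
    r_cut = np.quantile(richness[valid], 1.0 - top_frac, method="inverted_cdf")
    l_cut = np.quantile(loss[valid], bottom_frac, method="inverted_cdf")
    priority = valid & (richness >= r_cut) & (loss <= l_cut)
    gap = priority & ~pa.subset_mask(subset)
    rich_bin = quantile_classify(np.where(valid, richness, np.nan), n_bins)
    loss_bin = quantile_classify(np.where(valid, loss, np.nan), n_bins)
    return PriorityMap(pa.grid, rich_bin, loss_bin, priority, gap)


def country_gap_summary(
    gap: np.ndarray, partition: PartitionRasters, valid_mask: np.ndarray | None = None
) -> pd.DataFrame:
    """Per-country gap area (km^2) and gap percent of the country's area."""
    grid = partition.grid
    cell_area = grid.cell_area_km2
    valid = np.ones(grid.shape, bool) if valid_mask is None else valid_mask
    rows = []
    for cid in np.unique(partition.country_id[valid]):
        cmask = valid & (partition.country_id == cid)
        n_country = int(cmask.sum())
        if n_country == 0:
            continue
        n_gap = int((gap & cmask).sum())
        rows.append(
            {
                "country_id": int(cid),
                "gap_area_km2": n_gap * cell_area,
                "country_area_km2": n_country * cell_area,
                "gap_percent": 100.0 * n_gap / n_country,
            }
        )
    return pd.DataFrame(rows)
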