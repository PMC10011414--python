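"""Protected-area effectiveness metrics and summary statistics.

Species-level quantities derived by overlaying binary ranges on the PA class
raster: coverage fractions (strict Class I-IV vs all Class I-VI subsets),
percentage of species with any suitable habitat inside PAs, proportions of
species exceeding 15%/30% coverage benchmarks, rarity-weighted richness, and
range loss inside vs outside PAs under climate change, compared with Wilcoxon
tests (paired signed-rank for within-species strata, rank-sum for comparisons
across unequal species sets).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .ensemble import BinaryRange
from .landscape import PAMask

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# coverage

def coverage_fraction(range_: BinaryRange, pa: PAMask, subset: str = "strict") -> float:
    """Fraction of the range's cells whose PA class is in the subset."""
    n_range = range_.n_cells
    if n_range == 0:
        raise ValueError(
            f"{range_.species_id}: empty range; handle via the extinct path"
        )
    inside = int((range_.mask & pa.subset_mask(subset)).sum())
    return inside / n_range


def pct_species_protected(
    ranges: dict[str, BinaryRange], pa: PAMask, subset: str = "strict"
) -> float:
    """Percent of non-extinct species with >= 1 suitable cell inside PAs.

    Extinct species (empty future range) are excluded from the denominator.
    """
    alive = [r for r in ranges.values() if not r.extinct]
    if not alive:
        raise ValueError("no non-extinct species in this scenario")
    sub = pa.subset_mask(subset)
    n_prot = sum(1 for r in alive if (r.mask & sub).any())
    return 100.0 * n_prot / len(alive)


def benchmark_proportion(coverages, benchmark: float = 0.15) -> float:
    """Percent of species whose PA coverage strictly exceeds the benchmark."""
    cov = np.asarray(list(coverages), float)
    if cov.size == 0:
        raise ValueError("empty coverage list")
    if np.any((cov < 0) | (cov > 1)):
        raise ValueError("coverages must lie in [0, 1]")
    return 100.0 * float((cov > benchmark).mean())


# ---------------------------------------------------------------------------
# rarity-weighted richness

def rarity_weighted_richness(
    ranges: dict[str, BinaryRange],
    pa: PAMask,
    subset: str = "strict",
    mode: str = "species_sum",
) -> float | tuple[float, np.ndarray]:
    """Rarity-weighted richness: each species scores 1/range-size (in cells).

    ``species_sum``: sum of scores over species occurring (>= 1 cell) in PAs.
    ``cell_sum``: per-cell RWR raster (sum of scores of species present in the
    cell) plus its aggregate over PA cells; returns ``(aggregate, raster)``.
    """
    sub = pa.subset_mask(subset)
    alive = [r for r in ranges.values() if r.n_cells > 0]
    if mode == "species_sum":
        return float(
            sum(1.0 / r.n_cells for r in alive if (r.mask & sub).any())
        )
    if mode == "cell_sum":
        raster = np.zeros(pa.grid.shape)
        for r in alive:
            raster[r.mask] += 1.0 / r.n_cells
        return float(raster[sub].sum()), raster
    raise ValueError("mode must be 'species_sum' or 'cell_sum'")


# ---------------------------------------------------------------------------
# range change inside / outside PAs

def range_change_inside_outside(
    current: BinaryRange, future: BinaryRange, pa: PAMask, subset: str = "strict"
) -> tuple[float | None, float | None]:
    """Percent range loss inside and outside PAs (None where stratum is empty).

    Requires the no-dispersal containment future subset of current, so losses
    lie in [0, 100].
    """
    if np.any(future.mask & ~current.mask):
        raise ValueError("future range must be contained in current range")
    sub = pa.subset_mask(subset)
    res = []
    for stratum in (sub, ~sub):
        cur = int((current.mask & stratum).sum())
        if cur == 0:
            res.append(None)
        else:
            fut = int((future.mask & stratum).sum())
            res.append(100.0 * (cur - fut) / cur)
    return res[0], res[1]


# ---------------------------------------------------------------------------
# Wilcoxon tests

@dataclass
class WilcoxonResult:
    n_used: int
    statistic: float
    z: float
    p: float
    paired: bool


def _signed_rank_exact_p(w_plus: float, ranks: np.ndarray) -> float:
    """Exact two-sided p over all 2^n sign assignments of the ranks.

    The null distribution of W+ is built by dynamic programming on the
    doubled-rank lattice (average ranks under ties are half-integers), which
    is equivalent to full enumeration.
    """
    r2 = np.rint(2 * ranks).astype(int)
    counts = np.zeros(int(r2.sum()) + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    ws = np.arange(counts.size)
    mu2 = r2.sum() / 2.0
    obs = abs(2 * w_plus - mu2)
    return float(counts[np.abs(ws - mu2) >= obs - 1e-9].sum() / counts.sum())


def wilcoxon_signed_rank(x, y, exact_max_n: int = 12) -> WilcoxonResult:
    """Paired Wilcoxon signed-rank test (two-sided).

    Zero differences are dropped; tied absolute differences get average
    ranks.  For ``n <= exact_max_n`` the p-value is computed by exhaustive
    enumeration over all sign assignments (valid under ties); otherwise the
    tie-corrected normal approximation with continuity correction is used.
    The Z statistic (normal approximation, no continuity correction) is
    reported in both regimes and flips sign when all differences are negated.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        logger.warning("all differences zero; Wilcoxon degenerate")
        return WilcoxonResult(0, 0.0, 0.0, 1.0, True)
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    _, t_counts = np.unique(ranks, return_counts=True)
    tie_corr = np.sum(t_counts**3 - t_counts) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_corr
    z = 0.0 if var == 0 else (w_plus - mu) / np.sqrt(var)
    if n <= exact_max_n:
        p = _signed_rank_exact_p(w_plus, ranks)
    elif var == 0:
        p = 1.0
    else:
        zc = (w_plus - mu - 0.5 * np.sign(w_plus - mu)) / np.sqrt(var)
        p = 2.0 * sps.norm.sf(abs(zc))
    return WilcoxonResult(n, w_plus, float(z), float(min(p, 1.0)), paired=True)


def wilcoxon_rank_sum(x, y) -> WilcoxonResult:
    """Unpaired two-sided rank-sum (Mann-Whitney) test with normal Z."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    mu = x.size * y.size / 2.0
    n = x.size + y.size
    ranks = sps.rankdata(np.concatenate([x, y]))
    _, t = np.unique(ranks, return_counts=True)
    tie = ((t**3 - t).sum()) / (n * (n - 1))
    var = x.size * y.size / 12.0 * ((n + 1) - tie)
    z = 0.0 if var == 0 else (res.statistic - mu) / np.sqrt(var)
    return WilcoxonResult(n, float(res.statistic), float(z), float(res.pvalue), paired=False)


# ---------------------------------------------------------------------------
# species metrics table and group summaries

def build_species_metrics(
    ranges_by_scenario: dict[str, dict[str, BinaryRange]],
    pa: PAMask,
    partition=None,
    current_label: str = "current",
    attributes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One row per species x scenario with areas, coverages, and losses.

    ``attributes`` may carry a boolean ``threatened`` column indexed by
    species_id; the ``small_range`` flag (range area strictly below the
    median over species) is derived here from current range areas.
    """
    cell_area = pa.grid.cell_area_km2
    current = ranges_by_scenario[current_label]
    areas = {sp: r.n_cells * cell_area for sp, r in current.items()}
    med = float(np.median(list(areas.values()))) if areas else np.nan
    rows = []
    for scen, ranges in ranges_by_scenario.items():
        for sp, r in ranges.items():
            row: dict = {
                "species_id": sp,
                "scenario": scen,
                "extinct": r.extinct,
                "range_area_km2": r.n_cells * cell_area,
                "small_range": areas.get(sp, np.nan) < med,
                "threatened": (
                    bool(attributes.loc[sp, "threatened"])
                    if attributes is not None and sp in attributes.index
                    else False
                ),
            }
            for subset in ("strict", "all"):
                if r.n_cells > 0:
                    cov = coverage_fraction(r, pa, subset)
                    row[f"coverage_{subset}"] = cov
                    row[f"area_in_pa_{subset}_km2"] = cov * r.n_cells * cell_area
                else:
                    row[f"coverage_{subset}"] = np.nan
                    row[f"area_in_pa_{subset}_km2"] = np.nan
            if scen != current_label and sp in current:
                for subset in ("strict", "all"):
                    li, lo = range_change_inside_outside(current[sp], r, pa, subset)
                    row[f"loss_inside_{subset}_pct"] = np.nan if li is None else li
                    row[f"loss_outside_{subset}_pct"] = np.nan if lo is None else lo
            if partition is not None and r.n_cells > 0:
                row["regions"] = tuple(
                    np.unique(partition.region_id[r.mask]).tolist()
                )
            rows.append(row)
    return pd.DataFrame(rows)


def summarize_group(
    metrics: pd.DataFrame,
    group_by: str | None = None,
    benchmarks: tuple[float, ...] = (0.15, 0.30),
    subset: str = "strict",
) -> pd.DataFrame:
    """Per-group (and per-scenario) medians, quartiles and benchmark shares.

    ``group_by`` may be None (global), a boolean attribute column
    (``small_range``, ``threatened``) or ``'region'`` (a species counts in
    every region its range overlaps).
    """
    cov = f"coverage_{subset}"

    def _expand(df: pd.DataFrame) -> pd.DataFrame:
        if group_by is None:
            return df.assign(_group="global")
        if group_by == "region":
            df = df.dropna(subset=["regions"] if "regions" in df else [])
            return df.explode("regions").rename(columns={"regions": "_group"})
        return df.assign(_group=df[group_by])

    out = []
    for (scen, grp), sub_df in _expand(metrics).groupby(["scenario", "_group"]):
        alive = sub_df[~sub_df["extinct"]]
        row = {"scenario": scen, "group": grp, "n_species": len(alive)}
        if len(alive) == 0:
            row.update({"coverage_median": np.nan, "coverage_q25": np.nan,
                        "coverage_q75": np.nan, "pct_protected": np.nan})
        else:
            c = alive[cov].dropna()
            row["coverage_median"] = float(c.median())
            row["coverage_q25"] = float(c.quantile(0.25))
            row["coverage_q75"] = float(c.quantile(0.75))
            row["pct_protected"] = 100.0 * float((c > 0).mean())
            for b in benchmarks:
                row[f"pct_above_{int(b * 100)}"] = benchmark_proportion(c, b)
        out.append(row)
    return pd.DataFrame(out)
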