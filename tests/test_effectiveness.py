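"""PA coverage metrics, rarity-weighted richness, and Wilcoxon machinery."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from sdmgap.ensemble import BinaryRange
from sdmgap.grid import GridSpec
from sdmgap.landscape import PAMask
from sdmgap.effectiveness import (
    benchmark_proportion,
    build_species_metrics,
    coverage_fraction,
    pct_species_protected,
    range_change_inside_outside,
    rarity_weighted_richness,
    summarize_group,
    wilcoxon_rank_sum,
    wilcoxon_signed_rank,
)

GRID = GridSpec(5, 10)


def _range(cells, label="current"):
    mask = np.zeros(GRID.shape, bool)
    for r, c in cells:
        mask[r, c] = True
    return BinaryRange("sp", label, mask, 0.5)


def _pa(strict_cells=(), nonstrict_cells=()):
    classes = np.zeros(GRID.shape, np.int8)
    for r, c in strict_cells:
        classes[r, c] = 3  # II
    for r, c in nonstrict_cells:
        classes[r, c] = 6  # V
    return PAMask(GRID, classes)


class TestCoverage:
    def test_fully_inside_strict(self):
        cells = [(0, c) for c in range(5)]
        assert coverage_fraction(_range(cells), _pa(strict_cells=cells)) == 1.0

    def test_three_of_ten_in_class_ii(self):
        cells = [(r, c) for r in range(2) for c in range(5)]
        pa = _pa(strict_cells=cells[:3])
        r = _range(cells)
        assert coverage_fraction(r, pa, "strict") == pytest.approx(0.3)
        assert coverage_fraction(r, pa, "all") == pytest.approx(0.3)

    def test_strict_vs_all_subsets(self):
        cells = [(r, c) for r in range(2) for c in range(5)]
        pa = _pa(strict_cells=cells[:3], nonstrict_cells=cells[3:5])
        r = _range(cells)
        assert coverage_fraction(r, pa, "strict") == pytest.approx(0.3)
        assert coverage_fraction(r, pa, "all") == pytest.approx(0.5)

    def test_inside_plus_outside_is_one(self):
        rng = np.random.default_rng(0)
        classes = rng.integers(0, 8, GRID.shape).astype(np.int8)
        pa = PAMask(GRID, classes)
        mask = rng.random(GRID.shape) < 0.4
        mask[0, 0] = True
        r = BinaryRange("sp", "current", mask, 0.5)
        for subset in ("strict", "all"):
            inside = coverage_fraction(r, pa, subset)
            outside = (r.mask & ~pa.subset_mask(subset)).sum() / r.n_cells
            assert inside + outside == pytest.approx(1.0, abs=1e-12)

    def test_empty_range_directs_to_extinct_path(self):
        with pytest.raises(ValueError, match="extinct"):
            coverage_fraction(_range([]), _pa())


class TestPctProtected:
    def test_three_of_four_protected(self):
        pa = _pa(strict_cells=[(0, 0)])
        ranges = {
            "a": _range([(0, 0), (1, 1)]),
            "b": _range([(0, 0)]),
            "c": _range([(0, 0), (4, 4)]),
            "d": _range([(3, 3)]),
        }
        assert pct_species_protected(ranges, pa) == pytest.approx(75.0)

    def test_all_protected(self):
        pa = _pa(strict_cells=[(0, 0)])
        ranges = {k: _range([(0, 0)]) for k in "abc"}
        assert pct_species_protected(ranges, pa) == pytest.approx(100.0)

    def test_extinct_excluded_from_denominator(self):
        pa = _pa(strict_cells=[(0, 0)])
        ranges = {
            "a": _range([(0, 0)], "future"),
            "b": _range([(0, 0)], "future"),
            "c": _range([(0, 0)], "future"),
            "d": _range([(3, 3)], "future"),  # alive, unprotected
            "e": _range([], "future"),  # extinct
        }
        assert pct_species_protected(ranges, pa) == pytest.approx(75.0)


class TestBenchmark:
    def test_fifteen_percent(self):
        assert benchmark_proportion([0.20, 0.10, 0.50, 0.00], 0.15) == pytest.approx(50.0)

    def test_thirty_percent(self):
        assert benchmark_proportion([0.20, 0.10, 0.50, 0.00], 0.30) == pytest.approx(25.0)

    def test_boundary_value_not_counted(self):
        assert benchmark_proportion([0.15], 0.15) == 0.0


class TestRarityWeightedRichness:
    def test_single_species_inverse_range(self):
        cells = [(0, c) for c in range(10)]
        pa = _pa(strict_cells=[(0, 0)])
        assert rarity_weighted_richness({"a": _range(cells)}, pa) == pytest.approx(0.1)

    def test_unprotected_species_contributes_zero(self):
        pa = _pa(strict_cells=[(4, 9)])
        ranges = {"a": _range([(0, 0)]), "b": _range([(4, 9), (4, 8)])}
        assert rarity_weighted_richness(ranges, pa) == pytest.approx(0.5)

    def test_cell_sum_conservation_identity(self):
        rng = np.random.default_rng(1)
        ranges = {}
        for i in range(7):
            mask = rng.random(GRID.shape) < 0.3
            mask[i % 5, i] = True
            ranges[f"s{i}"] = BinaryRange(f"s{i}", "current", mask, 0.5)
        _, raster = rarity_weighted_richness(ranges, _pa(), mode="cell_sum")
        assert raster.sum() == pytest.approx(len(ranges), abs=1e-9)


class TestRangeChange:
    def test_no_change(self):
        cells = [(0, 0), (1, 1)]
        pa = _pa(strict_cells=[(0, 0)])
        li, lo = range_change_inside_outside(
            _range(cells), _range(cells, "future"), pa
        )
        assert (li, lo) == (0.0, 0.0)

    def test_constructed_losses(self):
        inside = [(0, c) for c in range(10)]
        outside = [(1, c) for c in range(10)]
        pa = _pa(strict_cells=inside)
        cur = _range(inside + outside)
        fut = _range(inside[:5] + outside[:2], "future")
        li, lo = range_change_inside_outside(cur, fut, pa)
        assert (li, lo) == (50.0, 80.0)

    def test_species_outside_pa_has_undefined_inside_loss(self):
        pa = _pa(strict_cells=[(4, 9)])
        cur = _range([(0, 0), (0, 1)])
        fut = _range([(0, 0)], "future")
        li, lo = range_change_inside_outside(cur, fut, pa)
        assert li is None and lo == pytest.approx(50.0)


def enumeration_p(d):
    """Exact two-sided signed-rank p by brute force over sign assignments."""
    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    mu = ranks.sum() / 2
    w_obs = ranks[d > 0].sum()
    hits = 0
    for signs in itertools.product([0, 1], repeat=len(d)):
        w = float(np.dot(signs, ranks))
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            hits += 1
    return hits / 2 ** len(d)


class TestWilcoxon:
    def test_all_zero_differences(self):
        x = np.arange(5.0)
        res = wilcoxon_signed_rank(x, x)
        assert (res.z, res.p) == (0.0, 1.0)

    def test_negation_flips_z_keeps_p(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        a = wilcoxon_signed_rank(x, y)
        b = wilcoxon_signed_rank(y, x)
        assert a.z == pytest.approx(-b.z)
        assert a.p == pytest.approx(b.p)

    def test_n6_matches_enumeration(self):
        x = np.array([3.1, 0.4, 2.2, -1.0, 5.5, 0.9])
        y = np.zeros(6)
        res = wilcoxon_signed_rank(x, y)
        assert res.p == pytest.approx(enumeration_p(x), abs=1e-10)

    def test_matches_scipy_asymptotic_without_ties(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0.4, 1, 40)
        y = rng.normal(0, 1, 40)
        ours = wilcoxon_signed_rank(x, y)
        ref = sps.wilcoxon(x, y, correction=True, method="approx")
        assert ours.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_normal_approx_close_to_exact_on_12_instances(self):
        # n = 18 pairs: the smallest size at which the continuity-corrected
        # normal approximation is within 0.01 of the exact p for every
        # possible statistic value
        rng = np.random.default_rng(4)
        for _ in range(12):
            d = rng.normal(0.3, 1.0, 18)
            exact = wilcoxon_signed_rank(d, np.zeros(18), exact_max_n=18).p
            approx = wilcoxon_signed_rank(d, np.zeros(18), exact_max_n=0).p
            assert abs(exact - approx) <= 0.01

    def test_rank_sum_variant(self):
        rng = np.random.default_rng(5)
        x = rng.normal(1.0, 1, 30)
        y = rng.normal(0.0, 1, 25)
        res = wilcoxon_rank_sum(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert res.p == pytest.approx(ref.pvalue)
        assert not res.paired


class TestGroupSummaries:
    def _metrics(self):
        ranges = {
            "current": {
                f"s{i}": BinaryRange(
                    f"s{i}", "current",
                    np.pad(np.ones((1, i + 1), bool),
                           ((0, 4), (0, 9 - i))), 0.5,
                )
                for i in range(4)
            }
        }
        pa = _pa(strict_cells=[(0, 0)])
        return build_species_metrics(ranges, pa)

    def test_small_range_flags_strictly_below_median(self):
        m = self._metrics().set_index("species_id")
        # areas 1,2,3,4 km^2 -> median 2.5 -> flags T,T,F,F
        assert m["small_range"].tolist() == [True, True, False, False]

    def test_group_of_one(self):
        m = self._metrics()
        m = m[m["species_id"] == "s0"]
        s = summarize_group(m)
        assert s["coverage_median"].iloc[0] == pytest.approx(1.0)
        assert s["coverage_q25"].iloc[0] == s["coverage_q75"].iloc[0]

    def test_region_grouping_counts_overlaps(self):
        grid = GRID
        regions = np.zeros(grid.shape, np.int32)
        regions[:, 5:] = 1
        from sdmgap.landscape import PartitionRasters

        part = PartitionRasters(grid, regions, np.zeros_like(regions))
        spanning = np.zeros(grid.shape, bool)
        spanning[0, 4:6] = True  # overlaps both regions
        ranges = {
            "current": {
                "a": BinaryRange("a", "current", spanning, 0.5),
                "b": _range([(0, 0)]),
            }
        }
        m = build_species_metrics(ranges, _pa(), partition=part)
        s = summarize_group(m, "region")
        assert s["n_species"].sum() == 3  # 2 species, one counted twice
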