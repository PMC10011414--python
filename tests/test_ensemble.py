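"""Ensemble SDM building blocks: calibration, splits, learners, scores, ranges."""

import numpy as np
import pytest

from sdmgap.grid import GridSpec
from sdmgap.landscape import PartitionRasters
from sdmgap.ensemble import (
    ModelRun,
    UnmodelableSpeciesError,
    binarize,
    build_calibration_area,
    ensemble_predict,
    evaluate_auc,
    evaluate_tss,
    fit_base_learners,
    max_tss_threshold,
    partition_train_test,
    project_future,
    sample_pseudo_absences,
    score_env,
)


def brute_force_auc(scores, truth):
    """O(n^2) all-pairs AUC."""
    pos = np.asarray(scores)[np.asarray(truth).astype(bool)]
    neg = np.asarray(scores)[~np.asarray(truth).astype(bool)]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def exhaustive_max_tss(scores, truth):
    """Scan every unique score as a >= threshold; smallest maximizer wins."""
    scores = np.asarray(scores, float)
    truth = np.asarray(truth).astype(bool)
    best = (None, -np.inf)
    for t in np.unique(scores):
        pred = scores >= t
        sens = pred[truth].mean()
        spec = (~pred[~truth]).mean()
        tss = sens + spec - 1
        if tss > best[1] + 1e-12:  # ties resolve to the smallest threshold
            best = (t, tss)
    return best


class TestCalibrationArea:
    def test_disk_matches_brute_force_scan(self, one_region_partition, grid50):
        presence = np.zeros(grid50.shape, bool)
        presence[25, 25] = True
        calib = build_calibration_area("sp", presence, one_region_partition, 10.0)
        rr, cc = np.mgrid[0:50, 0:50]
        brute = ((rr - 25) ** 2 + (cc - 25) ** 2) <= 100.0
        np.testing.assert_array_equal(calib.mask, brute)

    def test_unoccupied_region_excluded_within_buffer(self, grid50):
        regions = np.zeros(grid50.shape, dtype=np.int32)
        regions[:, 30:] = 1
        part = PartitionRasters(grid50, regions, np.zeros_like(regions))
        presence = np.zeros(grid50.shape, bool)
        presence[25, 20] = True  # 10 km from region 1 boundary, buffer 500 covers all
        calib = build_calibration_area("sp", presence, part, 500.0)
        assert not calib.mask[:, 30:].any()
        assert calib.mask[:, :30].all()

    def test_presences_always_inside(self, one_region_partition, grid50):
        rng = np.random.default_rng(0)
        presence = rng.random(grid50.shape) < 0.01
        presence[0, 0] = True
        calib = build_calibration_area("sp", presence, one_region_partition, 5.0)
        assert np.all(calib.mask[presence])

    def test_empty_presences_rejected(self, one_region_partition, grid50):
        with pytest.raises(ValueError, match="no presence"):
            build_calibration_area(
                "sp", np.zeros(grid50.shape, bool), one_region_partition
            )


class TestPseudoAbsences:
    def _calib(self, grid50, one_region_partition):
        presence = np.zeros(grid50.shape, bool)
        presence[10, 10] = True
        return build_calibration_area("sp", presence, one_region_partition, 8.0), presence

    def test_support(self, grid50, one_region_partition):
        calib, presence = self._calib(grid50, one_region_partition)
        idx = sample_pseudo_absences(calib, presence, 50, seed=1)
        flat_ok = (calib.mask & ~presence).ravel()
        assert flat_ok[idx].all()
        assert len(np.unique(idx)) == 50

    def test_full_complement(self, grid50, one_region_partition):
        calib, presence = self._calib(grid50, one_region_partition)
        avail = int((calib.mask & ~presence).sum())
        idx = sample_pseudo_absences(calib, presence, avail, seed=2)
        np.testing.assert_array_equal(
            np.sort(idx), np.flatnonzero((calib.mask & ~presence).ravel())
        )

    def test_uniformity_frequency(self):
        grid = GridSpec(1, 5)
        part = PartitionRasters(
            grid, np.zeros(grid.shape, np.int32), np.zeros(grid.shape, np.int32)
        )
        presence = np.zeros(grid.shape, bool)
        presence[0, 0] = True
        calib = build_calibration_area("sp", presence, part, 1000.0)
        counts = np.zeros(5)
        for s in range(10_000):
            idx = sample_pseudo_absences(calib, presence, 1, seed=s)
            counts[idx[0]] += 1
        shares = counts[1:] / 10_000  # 4 candidate cells
        assert np.all(np.abs(shares - 0.25) <= 0.02)


class TestTrainTestSplits:
    def test_seventy_thirty_sizes(self):
        y = np.array([1] * 5 + [0] * 5, bool)
        for tr, te in partition_train_test(y, 0.7, 5, seed=0):
            assert len(tr) == 7 and len(te) == 3

    def test_union_and_disjointness(self):
        rng = np.random.default_rng(1)
        y = rng.random(57) < 0.4
        for tr, te in partition_train_test(y, 0.7, 5, seed=2):
            assert len(np.intersect1d(tr, te)) == 0
            np.testing.assert_array_equal(np.sort(np.concatenate([tr, te])),
                                          np.arange(57))

    def test_stratified_both_classes_everywhere(self):
        y = np.array([1] * 3 + [0] * 37, bool)
        for tr, te in partition_train_test(y, 0.7, 5, seed=3):
            assert y[tr].any() and not y[tr].all()
            assert y[te].any() and not y[te].all()

    def test_replicates_differ(self):
        y = np.arange(100) < 50
        splits = partition_train_test(y, 0.7, 5, seed=4)
        trains = [tuple(tr) for tr, _ in splits]
        assert len(set(trains)) == 5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="two records of each"):
            partition_train_test(np.ones(10, bool))


@pytest.fixture(scope="module")
def separable():
    rng = np.random.default_rng(5)
    X = np.vstack([rng.normal(-2, 1, (100, 2)), rng.normal(2, 1, (100, 2))])
    y = np.arange(200) >= 100
    return X, y


class TestBaseLearners:

    def test_all_learners_separate_gaussian_clouds(self, separable):
        X, y = separable
        for name, est in fit_base_learners(X, y, seed=0).items():
            auc = evaluate_auc(score_env(est, X), y)
            assert auc >= 0.95, name

    def test_deterministic_under_seed(self, separable):
        X, y = separable
        probe = np.array([[0.3, -0.2]])
        a = {n: score_env(e, probe)[0] for n, e in fit_base_learners(X, y, seed=7).items()}
        b = {n: score_env(e, probe)[0] for n, e in fit_base_learners(X, y, seed=7).items()}
        assert a == b

    def test_constant_column_tolerated(self, separable):
        X, y = separable
        X2 = np.column_stack([X, np.ones(len(X))])
        for name, est in fit_base_learners(X2, y, seed=1).items():
            assert np.all(np.isfinite(score_env(est, X2))), name

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single-class"):
            fit_base_learners(np.zeros((10, 2)), np.ones(10, bool))


class TestTss:
    def test_perfect_prediction(self):
        y = np.array([1, 1, 0, 0], bool)
        assert evaluate_tss(y, y) == pytest.approx(1.0)

    def test_all_presence_prediction(self):
        y = np.array([1, 1, 0, 0], bool)
        assert evaluate_tss(np.ones(4, bool), y) == pytest.approx(0.0)

    def test_constructed_confusion_counts(self):
        # sens 9/10, spec 8/10 -> TSS 0.7
        truth = np.array([True] * 10 + [False] * 10)
        pred = np.array([True] * 9 + [False] + [True] * 2 + [False] * 8)
        assert evaluate_tss(pred, truth) == pytest.approx(0.7)

    def test_one_class_truth_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            evaluate_tss(np.ones(4, bool), np.ones(4, bool))


class TestAuc:
    def test_perfect_and_inverted(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        truth = np.array([1, 1, 0, 0], bool)
        assert evaluate_auc(scores, truth) == 1.0
        assert evaluate_auc(scores, ~truth) == 0.0

    def test_ties_match_pairwise_oracle(self):
        rng = np.random.default_rng(6)
        scores = rng.integers(0, 10, 50) / 10.0  # heavy ties
        truth = rng.random(50) < 0.5
        truth[0], truth[1] = True, False
        assert evaluate_auc(scores, truth) == pytest.approx(
            brute_force_auc(scores, truth), abs=1e-12
        )


class TestMaxTss:
    def test_separable_smallest_maximizer(self):
        scores = np.array([0.9] * 5 + [0.1] * 5)
        truth = np.array([True] * 5 + [False] * 5)
        thr, tss = max_tss_threshold(scores, truth)
        assert (thr, tss) == (0.9, 1.0)

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            scores = rng.random(30).round(1)
            truth = rng.random(30) < 0.5
            truth[:2] = [True, False]
            thr, tss = max_tss_threshold(scores, truth)
            bthr, btss = exhaustive_max_tss(scores, truth)
            assert thr == bthr and tss == pytest.approx(btss, abs=1e-12)

    def test_degenerate_identical_scores(self):
        thr, tss = max_tss_threshold(np.full(6, 0.4), np.array([1, 0] * 3, bool))
        assert (thr, tss) == (0.4, 0.0)


def _run(tss, preds):
    return ModelRun("sp", "GLM", 1, tss, 0.9, tss >= 0.7,
                    {"current": np.asarray(preds, float)})


class TestEnsemble:
    def test_low_tss_run_excluded(self):
        runs = [_run(0.6, [1.0]), _run(0.8, [0.0])]
        out = ensemble_predict(runs, "current", 0.7)
        assert out[0] == 0.0  # only the 0.8 run contributes

    def test_weighted_average_arithmetic(self):
        runs = [_run(0.9, [0.2]), _run(0.7, [0.8])]
        out = ensemble_predict(runs, "current", 0.7)
        assert out[0] == pytest.approx((0.9 * 0.2 + 0.7 * 0.8) / 1.6)

    def test_convexity_when_runs_agree(self):
        runs = [_run(0.9, [0.55]), _run(0.8, [0.55]), _run(0.75, [0.55])]
        assert ensemble_predict(runs, "current")[0] == pytest.approx(0.55)

    def test_zero_retained_raises(self):
        with pytest.raises(UnmodelableSpeciesError):
            ensemble_predict([_run(0.5, [0.2])], "current", 0.7)

    def test_lowering_retention_never_drops_runs(self):
        runs = [_run(t, [0.5]) for t in (0.6, 0.72, 0.9)]
        kept_hi = {id(r) for r in runs if r.tss >= 0.7}
        kept_lo = {id(r) for r in runs if r.tss >= 0.5}
        assert kept_hi <= kept_lo


class TestBinaryRanges:
    def test_cell_at_threshold_is_presence(self):
        suit = np.array([[0.5, 0.49]])
        br = binarize(suit, 0.5, "sp", "current")
        assert br.mask.tolist() == [[True, False]]

    def test_count_matches_raster_scan(self):
        rng = np.random.default_rng(8)
        suit = rng.random((20, 20))
        br = binarize(suit, 0.62, "sp", "current")
        brute = sum(
            1 for r in range(20) for c in range(20) if suit[r, c] >= 0.62
        )
        assert br.n_cells == brute

    def test_no_dispersal_blocks_new_habitat(self):
        cur = binarize(np.array([[0.9, 0.1]]), 0.5, "sp", "current")
        fut = project_future(cur, np.array([[0.9, 0.9]]), 0.5)
        assert fut.mask.tolist() == [[True, False]]  # newly suitable cell not occupied

    def test_containment_property(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            cur = binarize(rng.random((10, 10)), 0.5, "sp", "current")
            fut = project_future(cur, rng.random((10, 10)), 0.5)
            assert not np.any(fut.mask & ~cur.mask)

    def test_extinct_flag(self):
        cur = binarize(np.array([[0.9]]), 0.5, "sp", "current")
        fut = project_future(cur, np.array([[0.1]]), 0.5)
        assert fut.extinct and fut.n_cells == 0
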