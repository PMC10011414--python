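"""Per-species ensemble distribution modelling.

For each species the pipeline: delimits a calibration area (occupied
zoogeographic regions intersected with a 500 km buffer around presences),
draws random pseudo-absences there, makes five stratified 70/30 train/test
replicates, fits five base learners (GLM, GBM, MaxEnt-style regularized
logistic, random forest, SVM), scores each algorithm x replicate run by test
TSS and AUC, keeps runs with TSS >= 0.7, averages their predictions weighted
by TSS, cuts the ensemble at the threshold that maximizes TSS, and projects
the binary range to future climates under the no-dispersal assumption
(future range = future-suitable cells intersected with the current range;
newly suitable cells are never colonized).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import PolynomialFeatures, StandardScaler
from sklearn.svm import SVC

from .landscape import ClimateStack, PartitionRasters
from .predictors import vif_filter_stack

logger = logging.getLogger(__name__)

ALGORITHMS = ("GLM", "GBM", "MaxEnt", "RF", "SVM")


class UnmodelableSpeciesError(ValueError):
    """No model run reached the TSS retention minimum for this species."""


# ---------------------------------------------------------------------------
# calibration area and pseudo-absences

@dataclass
class CalibrationArea:
    """Spatial domain in which a species' models are trained and projected."""

    species_id: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        if not self.mask.any():
            raise ValueError(f"{self.species_id}: empty calibration area")


def build_calibration_area(
    species_id: str,
    presence_mask: np.ndarray,
    partition: PartitionRasters,
    buffer_km: float = 500.0,
    valid_mask: np.ndarray | None = None,
) -> CalibrationArea:
    """Occupied regions intersected with a distance buffer around presences.

    A cell belongs to the calibration area iff its region holds at least one
    presence cell and its centre lies within ``buffer_km`` of some
    presence-cell centre.
    """
    if not presence_mask.any():
        raise ValueError(f"{species_id}: no presence cells")
    grid = partition.grid
    occupied = np.unique(partition.region_id[presence_mask])
    region_ok = np.isin(partition.region_id, occupied)
    # exact centre-to-centre Euclidean distance to the nearest presence cell
    dist_cells = distance_transform_edt(~presence_mask)
    mask = region_ok & (dist_cells * grid.cell_size_km <= buffer_km)
    if valid_mask is not None:
        mask &= valid_mask
    mask |= presence_mask  # invariant: every presence cell is in the area
    return CalibrationArea(species_id, mask)


def sample_pseudo_absences(
    calib: CalibrationArea, presence_mask: np.ndarray, n_pa: int, seed: int = 0
) -> np.ndarray:
    """Uniform draw without replacement of background cells (flat indices)."""
    candidates = np.flatnonzero((calib.mask & ~presence_mask).ravel())
    if candidates.size == 0:
        raise ValueError(f"{calib.species_id}: no background cells available")
    if n_pa > candidates.size:
        logger.warning(
            "%s: requested %d pseudo-absences, only %d cells available",
            calib.species_id, n_pa, candidates.size,
        )
        n_pa = candidates.size
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(candidates, size=n_pa, replace=False))


# ---------------------------------------------------------------------------
# train/test replication

def partition_train_test(
    y: np.ndarray, train_frac: float = 0.7, n_rep: int = 5, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified random train/test splits, repeated ``n_rep`` times.

    Each replicate puts ``round(train_frac * n)`` records in the training set,
    allocating per class proportionally while guaranteeing at least one train
    and one test record of every class.
    """
    y = np.asarray(y)
    n = y.size
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("need at least two records of each label")
    n_train_total = int(np.floor(train_frac * n + 0.5))
    # per-class allocation, adjusted to hit the total exactly
    alloc = {c: int(np.floor(train_frac * m + 0.5)) for c, m in zip(classes, counts)}
    for c, m in zip(classes, counts):
        alloc[c] = min(max(alloc[c], 1), m - 1)
    order = sorted(classes, key=lambda c: -counts[list(classes).index(c)])
    while sum(alloc.values()) > n_train_total:
        c = max(order, key=lambda c: alloc[c])
        if alloc[c] > 1:
            alloc[c] -= 1
        else:
            break
    while sum(alloc.values()) < n_train_total:
        grow = [c for c, m in zip(classes, counts) if alloc[c] < m - 1]
        if not grow:
            break
        c = max(grow, key=lambda c: counts[list(classes).index(c)] - alloc[c])
        alloc[c] += 1
    rng = np.random.default_rng(seed)
    splits = []
    for _ in range(n_rep):
        train_idx: list[np.ndarray] = []
        test_idx: list[np.ndarray] = []
        for c in classes:
            idx = np.flatnonzero(y == c)
            perm = rng.permutation(idx)
            train_idx.append(perm[: alloc[c]])
            test_idx.append(perm[alloc[c]:])
        splits.append(
            (np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx)))
        )
    return splits


# ---------------------------------------------------------------------------
# base learners

@dataclass
class LearnerSpec:
    """Algorithm name plus hyperparameter overrides."""

    name: str
    params: dict = field(default_factory=dict)


def make_learner(spec: LearnerSpec, seed: int = 0):
    """Instantiate one of the five base learners with documented defaults.

    GLM is a logistic regression on linear + quadratic terms (the classic
    niche-shaped GLM); MaxEnt is approximated by an L1-regularized logistic
    regression on a degree-2 feature expansion, the standard presence/
    background reduction of maximum entropy modelling.
    """
    name, p = spec.name, spec.params
    if name == "GLM":
        # logistic regression on a full degree-2 response surface (linear,
        # quadratic and pairwise-product terms), the classic niche-shaped GLM
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("poly", PolynomialFeatures(degree=p.get("degree", 2), include_bias=False)),
                ("clf", LogisticRegression(max_iter=2000, C=p.get("C", 1.0))),
            ]
        )
    if name == "MaxEnt":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("poly", PolynomialFeatures(degree=p.get("degree", 2), include_bias=False)),
                (
                    "clf",
                    LogisticRegression(
                        penalty="l1", solver="liblinear", C=p.get("C", 1.0),
                        max_iter=1000, random_state=seed,
                    ),
                ),
            ]
        )
    if name == "GBM":
        return GradientBoostingClassifier(
            n_estimators=p.get("n_estimators", 100),
            learning_rate=p.get("learning_rate", 0.1),
            max_depth=p.get("max_depth", 3),
            random_state=seed,
        )
    if name == "RF":
        return RandomForestClassifier(
            n_estimators=p.get("n_estimators", 100),
            min_samples_leaf=p.get("min_samples_leaf", 2),
            random_state=seed,
            n_jobs=1,
        )
    if name == "SVM":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "clf",
                    SVC(
                        kernel=p.get("kernel", "rbf"), C=p.get("C", 10.0),
                        gamma=p.get("gamma", "scale"), probability=True,
                        random_state=seed,
                    ),
                ),
            ]
        )
    raise ValueError(f"unknown algorithm {name!r}")


def fit_base_learners(
    X: np.ndarray, y: np.ndarray, specs: list[LearnerSpec] | None = None, seed: int = 0
) -> dict[str, object]:
    """Fit the base learners; each returns presence probability via ``score_env``."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("single-class training data")
    if np.isnan(X).any():
        raise ValueError("missing predictor values")
    for j in range(X.shape[1]):
        if np.ptp(X[:, j]) == 0:
            logger.info("constant predictor column %d tolerated", j)
    specs = specs or [LearnerSpec(a) for a in ALGORITHMS]
    fitted = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for spec in specs:
            est = make_learner(spec, seed=seed)
            est.fit(X, y)
            fitted[spec.name] = est
    return fitted


def score_env(est, X: np.ndarray) -> np.ndarray:
    """Presence probability in [0, 1] for environment vectors."""
    return est.predict_proba(X)[:, 1]


# ---------------------------------------------------------------------------
# evaluation

def evaluate_tss(predicted: np.ndarray, truth: np.ndarray) -> float:
    """True skill statistic = sensitivity + specificity - 1."""
    truth = np.asarray(truth).astype(bool)
    predicted = np.asarray(predicted).astype(bool)
    if truth.size != predicted.size:
        raise ValueError("length mismatch")
    if truth.all() or not truth.any():
        raise ValueError("truth must contain both classes")
    sens = predicted[truth].mean()
    spec = (~predicted[~truth]).mean()
    return float(sens + spec - 1.0)


def evaluate_auc(scores: np.ndarray, truth: np.ndarray) -> float:
    """Rank-based AUC: P(score+ > score-) + 0.5 P(score+ = score-)."""
    truth = np.asarray(truth).astype(bool)
    if truth.all() or not truth.any():
        raise ValueError("truth must contain both classes")
    return float(roc_auc_score(truth, np.asarray(scores, float)))


def max_tss_threshold(scores: np.ndarray, truth: np.ndarray) -> tuple[float, float]:
    """Threshold (from the unique score values) maximizing TSS.

    The prediction rule is ``score >= threshold -> presence``; among equal
    maximizers the smallest threshold is returned.  If all scores are
    identical TSS is 0 and that score is returned with a warning.
    """
    scores = np.asarray(scores, float)
    truth = np.asarray(truth).astype(bool)
    if truth.all() or not truth.any():
        raise ValueError("truth must contain both classes")
    uniq = np.unique(scores)
    if uniq.size == 1:
        logger.warning("all scores identical; degenerate maxTSS threshold")
        return float(uniq[0]), 0.0
    pos = np.sort(scores[truth])
    neg = np.sort(scores[~truth])
    # integer confusion counts so TSS ties are detected exactly:
    # sens(t) = #{pos >= t}/P ; spec(t) = #{neg < t}/N
    n_pos_ge = pos.size - np.searchsorted(pos, uniq, side="left")
    n_neg_lt = np.searchsorted(neg, uniq, side="left")
    numer = n_pos_ge * neg.size + n_neg_lt * pos.size - pos.size * neg.size
    best = int(np.argmax(numer))  # first (= smallest threshold) among maximizers
    return float(uniq[best]), float(numer[best] / (pos.size * neg.size))


# ---------------------------------------------------------------------------
# ensemble and binary ranges

@dataclass
class ModelRun:
    """One algorithm x replicate run with its test scores and predictions."""

    species_id: str
    algorithm: str
    replicate: int
    tss: float
    auc: float
    retained: bool
    predictions: dict[str, np.ndarray] = field(default_factory=dict)  # scenario -> calib-cell scores

    def __post_init__(self) -> None:
        if not -1.0 <= self.tss <= 1.0:
            raise ValueError("TSS out of [-1, 1]")
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("AUC out of [0, 1]")


def ensemble_predict(
    runs: list[ModelRun], scenario: str, retention_min: float = 0.7
) -> np.ndarray:
    """TSS-weighted average of retained runs' predictions for one scenario."""
    kept = [r for r in runs if r.tss >= retention_min]
    if not kept:
        sp = runs[0].species_id if runs else "?"
        raise UnmodelableSpeciesError(f"{sp}: no run reached TSS >= {retention_min}")
    w = np.array([r.tss for r in kept], float)
    w = w / w.sum()
    return np.einsum("i,ij->j", w, np.vstack([r.predictions[scenario] for r in kept]))


@dataclass
class BinaryRange:
    """Presence/absence raster for one species and scenario."""

    species_id: str
    scenario_label: str
    mask: np.ndarray
    threshold: float
    extinct: bool = False

    def __post_init__(self) -> None:
        self.extinct = not bool(self.mask.any())

    @property
    def n_cells(self) -> int:
        return int(self.mask.sum())


def binarize(
    suitability: np.ndarray,
    threshold: float,
    species_id: str,
    scenario_label: str,
    valid_mask: np.ndarray | None = None,
) -> BinaryRange:
    """Presence where suitability >= threshold (masked cells always absent)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    mask = suitability >= threshold
    if valid_mask is not None:
        mask &= valid_mask
    return BinaryRange(species_id, scenario_label, mask, threshold)


def project_future(
    current: BinaryRange, future_suitability: np.ndarray, threshold: float
) -> BinaryRange:
    """No-dispersal projection: future range = future-suitable AND currently occupied."""
    if future_suitability.shape != current.mask.shape:
        raise ValueError("grid mismatch between current range and future suitability")
    mask = (future_suitability >= threshold) & current.mask
    return BinaryRange(current.species_id, "future", mask, threshold)


# ---------------------------------------------------------------------------
# per-species orchestration

@dataclass
class SDMSettings:
    """Tunables of the per-species modelling stage."""

    algorithms: tuple[str, ...] = ALGORITHMS
    learner_params: dict[str, dict] = field(default_factory=dict)
    n_pseudo_absence: int | None = None  # None -> max(n_presence, 1000)
    retention_min: float = 0.7
    train_frac: float = 0.7
    n_rep: int = 5
    calibration_buffer_km: float = 500.0
    vif_threshold: float = 10.0
    vif_sample_cells: int = 10_000


@dataclass
class SpeciesSDMResult:
    """Everything the downstream PA analysis needs for one species."""

    species_id: str
    status: str  # 'ok' or 'unmodelable'
    runs: pd.DataFrame
    kept_variables: list[str]
    vif_removed: list[str] = field(default_factory=list)
    final_vifs: dict[str, float] = field(default_factory=dict)
    threshold: float | None = None
    suitability: dict[str, np.ndarray] | None = None  # scenario -> full-grid raster
    ranges: dict[str, "BinaryRange"] | None = None


def _env_matrix(stack: ClimateStack, variables: list[str], flat_idx: np.ndarray) -> np.ndarray:
    return np.column_stack([stack.layers[v].ravel()[flat_idx] for v in variables])


def fit_species_sdm(
    species_id: str,
    presence_mask: np.ndarray,
    stacks: dict[str, ClimateStack],
    partition: PartitionRasters,
    settings: SDMSettings | None = None,
    seed: int = 0,
    current_label: str = "current",
) -> SpeciesSDMResult:
    """Run the full per-species modelling chain on every scenario in ``stacks``."""
    s = settings or SDMSettings()
    current = stacks[current_label]
    grid = current.grid
    rng = np.random.default_rng(seed)

    calib = build_calibration_area(
        species_id, presence_mask, partition, s.calibration_buffer_km, current.valid_mask
    )
    kept_vars, vif_removed, final_vifs = vif_filter_stack(
        current, s.vif_threshold, calib.mask, s.vif_sample_cells,
        seed=int(rng.integers(2**31)),
    )
    pres_idx = np.flatnonzero(presence_mask.ravel())
    n_pa = s.n_pseudo_absence or max(pres_idx.size, 1000)
    pa_idx = sample_pseudo_absences(calib, presence_mask, n_pa, seed=int(rng.integers(2**31)))
    cell_idx = np.concatenate([pres_idx, pa_idx])
    y = np.concatenate([np.ones(pres_idx.size, bool), np.zeros(pa_idx.size, bool)])
    X = _env_matrix(current, kept_vars, cell_idx)

    calib_idx = np.flatnonzero(calib.mask.ravel())
    env_by_scenario = {lab: _env_matrix(st, kept_vars, calib_idx) for lab, st in stacks.items()}

    splits = partition_train_test(y, s.train_frac, s.n_rep, seed=int(rng.integers(2**31)))
    specs = [LearnerSpec(a, s.learner_params.get(a, {})) for a in s.algorithms]
    runs: list[ModelRun] = []
    for rep, (tr, te) in enumerate(splits, start=1):
        fitted = fit_base_learners(X[tr], y[tr], specs, seed=int(rng.integers(2**31)))
        for alg, est in fitted.items():
            test_scores = score_env(est, X[te])
            thr, tss = max_tss_threshold(test_scores, y[te])
            auc = evaluate_auc(test_scores, y[te])
            retained = tss >= s.retention_min
            preds = (
                {lab: score_env(est, env) for lab, env in env_by_scenario.items()}
                if retained
                else {}
            )
            runs.append(ModelRun(species_id, alg, rep, tss, auc, retained, preds))

    run_table = pd.DataFrame(
        [
            {
                "species_id": r.species_id, "algorithm": r.algorithm,
                "replicate": r.replicate, "tss": r.tss, "auc": r.auc,
                "retained": r.retained,
            }
            for r in runs
        ]
    )
    try:
        ens = {
            lab: ensemble_predict(runs, lab, s.retention_min) for lab in stacks
        }
    except UnmodelableSpeciesError:
        logger.warning("%s: unmodelable (no run with TSS >= %.2f)", species_id, s.retention_min)
        return SpeciesSDMResult(
            species_id, "unmodelable", run_table, kept_vars, vif_removed, final_vifs
        )

    # full-grid suitability rasters (0 outside the calibration area)
    suit = {}
    for lab in stacks:
        full = np.zeros(grid.n_cells)
        full[calib_idx] = ens[lab]
        suit[lab] = full.reshape(grid.shape)

    # maxTSS threshold on the pooled presence/pseudo-absence set under the ensemble
    pos_in_calib = np.searchsorted(calib_idx, cell_idx)
    pooled_scores = ens[current_label][pos_in_calib]
    threshold, _ = max_tss_threshold(pooled_scores, y)

    ranges = {
        current_label: binarize(
            suit[current_label], threshold, species_id, current_label, current.valid_mask
        )
    }
    for lab in stacks:
        if lab == current_label:
            continue
        fut = project_future(ranges[current_label], suit[lab], threshold)
        fut.scenario_label = lab
        ranges[lab] = fut
    return SpeciesSDMResult(
        species_id, "ok", run_table, kept_vars, vif_removed, final_vifs,
        threshold, suit, ranges,
    )
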