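"""Predictor preparation: multi-GCM averaging and multicollinearity screening.

Future climate layers are averaged cell-wise across circulation models, and
the predictor set for each species is screened for multicollinearity with
variance inflation factors (VIF): variables are removed one at a time,
worst first, until every remaining VIF is below the threshold (default 10,
the conventional cut-off).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .landscape import ClimateStack

logger = logging.getLogger(__name__)

#: VIF reported for perfectly collinear variables (documented cap for R^2 -> 1)
VIF_CAP = 1e12


def average_gcms(stacks: list[ClimateStack]) -> ClimateStack:
    """Cell-wise arithmetic mean of co-registered stacks (one per GCM).

    A cell masked in any input is masked in the output.
    """
    if not stacks:
        raise ValueError("need at least one stack")
    first = stacks[0]
    for s in stacks[1:]:
        if s.grid != first.grid:
            raise ValueError("grid mismatch between stacks")
        if set(s.layers) != set(first.layers):
            raise ValueError("variable sets differ between stacks")
    mask = np.zeros(first.grid.shape, bool)
    for s in stacks:
        mask |= s.nodata_mask
    layers = {
        v: np.mean([s.layers[v] for s in stacks], axis=0) for v in first.layers
    }
    return ClimateStack(first.grid, first.scenario_label, layers, mask)


@dataclass
class PredictorSample:
    """Environment values at sampled cells: rows = cells, columns = variables."""

    matrix: np.ndarray
    variables: tuple[str, ...]
    source_cells: np.ndarray | None = None  # flat cell indices, optional

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.variables):
            raise ValueError("matrix must be n_cells x n_variables")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("predictor sample contains missing values")
        if self.matrix.shape[0] <= self.matrix.shape[1] + 1:
            raise ValueError("need more sampled cells than variables + 1")

    def drop(self, variable: str) -> "PredictorSample":
        j = self.variables.index(variable)
        keep = [i for i in range(len(self.variables)) if i != j]
        return PredictorSample(
            self.matrix[:, keep],
            tuple(v for i, v in enumerate(self.variables) if i in set(keep)),
            self.source_cells,
        )


def sample_predictors(
    stack: ClimateStack,
    cell_mask: np.ndarray | None = None,
    n_sample_cells: int = 10_000,
    seed: int = 0,
) -> PredictorSample:
    """Draw a random cell sample (without replacement) of predictor values.

    ``cell_mask`` restricts the candidate cells (e.g. to a species'
    calibration area); the sample size is capped at the available cells.
    """
    valid = stack.valid_mask if cell_mask is None else (stack.valid_mask & cell_mask)
    idx = np.flatnonzero(valid.ravel())
    if idx.size == 0:
        raise ValueError("no valid cells to sample")
    rng = np.random.default_rng(seed)
    take = min(n_sample_cells, idx.size)
    chosen = np.sort(rng.choice(idx, size=take, replace=False))
    variables = tuple(stack.layers)
    mat = np.column_stack([stack.layers[v].ravel()[chosen] for v in variables])
    return PredictorSample(mat, variables, chosen)


def compute_vif(sample: PredictorSample, variable: str) -> float:
    """VIF = 1/(1 - R^2) of ``variable`` regressed (with intercept) on the rest.

    Perfect collinearity is reported as a large finite cap, not an exception.
    """
    j = sample.variables.index(variable)
    y = sample.matrix[:, j]
    others = np.delete(sample.matrix, j, axis=1)
    if others.shape[1] == 0:
        return 1.0
    X = np.column_stack([np.ones(len(y)), others])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        return float(VIF_CAP)
    r2 = 1.0 - np.sum(resid**2) / ss_tot
    if r2 >= 1.0 - 1.0 / VIF_CAP:
        return float(VIF_CAP)
    return float(1.0 / (1.0 - r2))


def vif_filter(
    sample: PredictorSample, threshold: float = 10.0
) -> tuple[list[str], list[str], dict[str, float]]:
    """Stepwise VIF screening: drop the worst variable until all VIF < threshold.

    Ties are broken by the fixed variable-name order of the sample.  Returns
    ``(kept, removal_order, final_vifs)``.  Stops with a warning if fewer than
    two variables would remain.
    """
    if threshold <= 1.0:
        raise ValueError("threshold must exceed 1")
    cur = sample
    removed: list[str] = []
    while True:
        vifs = {v: compute_vif(cur, v) for v in cur.variables}
        worst = max(vifs, key=lambda v: (vifs[v]))
        if vifs[worst] < threshold:
            break
        if len(cur.variables) <= 2:
            logger.warning("vif_filter: only two variables left; stopping early")
            break
        removed.append(worst)
        cur = cur.drop(worst)
    return list(cur.variables), removed, {v: compute_vif(cur, v) for v in cur.variables}


def vif_filter_stack(
    stack: ClimateStack,
    threshold: float = 10.0,
    cell_mask: np.ndarray | None = None,
    n_sample_cells: int = 10_000,
    seed: int = 0,
) -> tuple[list[str], list[str], dict[str, float]]:
    """Convenience wrapper: sample cells from a stack, then run the VIF screen."""
    sample = sample_predictors(stack, cell_mask, n_sample_cells, seed)
    return vif_filter(sample, threshold)
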