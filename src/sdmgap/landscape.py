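"""Synthetic landscape generation: climate, virtual species, sampling, PAs.

This module builds a fully synthetic study system with known ground truth so
the whole modelling pipeline can be exercised and validated without any
external data.  It emulates the statistical character of the real inputs:

* six spatially autocorrelated bioclimatic layers (BIO1 annual mean
  temperature, BIO3 isothermality, BIO5/BIO6 warm/cold extremes, BIO12 annual
  precipitation, BIO18 warm-quarter precipitation) under a current and a
  shifted future scenario, with the temperature ordering BIO6 <= BIO1 <= BIO5
  and 0 <= BIO18 <= BIO12 enforced by construction;
* virtual species whose suitability is a product of per-variable Gaussian
  responses, so the true range is known exactly;
* biased presence-only sampling with replacement (raw-database style);
* a protected-area network of contiguous patches with IUCN-style classes
  Ia-VI, optionally placed preferentially in climate-stable cells;
* zoogeographic-region and country partitions of the grid (connected labelled
  blobs).

Every generator is a pure function of its parameters and a seed.
"""

from __future__ import annotations

import heapq
from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .grid import GridSpec
from .occurrences import OccurrenceSet

CLIMATE_VARS = ("BIO1", "BIO3", "BIO5", "BIO6", "BIO12", "BIO18")

#: PA class codes used in the integer class raster
PA_CLASSES = ("none", "Ia", "Ib", "II", "III", "IV", "V", "VI")
PA_CODE = {name: i for i, name in enumerate(PA_CLASSES)}
STRICT_CLASSES = ("Ia", "Ib", "II", "III", "IV")  # IUCN I-IV
ALL_CLASSES = ("Ia", "Ib", "II", "III", "IV", "V", "VI")  # IUCN I-VI


class UnsampleableSpeciesError(ValueError):
    """Raised when a species' true range is empty and cannot be sampled."""


# ---------------------------------------------------------------------------
# climate

@dataclass
class ClimateStack:
    """Co-registered bioclimatic layers for one scenario."""

    grid: GridSpec
    scenario_label: str
    layers: dict[str, np.ndarray]
    nodata_mask: np.ndarray | None = None  # True where no data

    def __post_init__(self) -> None:
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.grid.shape, dtype=bool)
        for name, arr in self.layers.items():
            if arr.shape != self.grid.shape:
                raise ValueError(f"layer {name} shape {arr.shape} != grid {self.grid.shape}")
        self.validate()

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(self.layers)

    @property
    def valid_mask(self) -> np.ndarray:
        return ~self.nodata_mask

    def validate(self) -> None:
        ok = self.valid_mask
        L = self.layers
        if {"BIO1", "BIO5", "BIO6"} <= set(L):
            if np.any(L["BIO6"][ok] > L["BIO1"][ok]) or np.any(L["BIO1"][ok] > L["BIO5"][ok]):
                raise ValueError("temperature ordering BIO6 <= BIO1 <= BIO5 violated")
        if "BIO12" in L and np.any(L["BIO12"][ok] < 0):
            raise ValueError("BIO12 must be non-negative")
        if {"BIO12", "BIO18"} <= set(L):
            if np.any(L["BIO18"][ok] < 0) or np.any(L["BIO18"][ok] > L["BIO12"][ok] + 1e-9):
                raise ValueError("0 <= BIO18 <= BIO12 violated")


@dataclass
class ClimateFieldParams:
    """Statistical character of the synthetic climate fields.

    ``correlation_length_km`` sets the e-folding scale of spatial
    autocorrelation (smoothed-noise construction).  Means and spreads are in
    the units of the variables (degC for temperatures, mm for precipitation).
    """

    correlation_length_km: float = 10.0
    bio1_mean: float = 15.0
    bio1_spread: float = 8.0
    bio3_mean: float = 45.0
    bio3_spread: float = 10.0
    temp_offset_mean: float = 10.0  # BIO5 = BIO1 + offset, BIO6 = BIO1 - offset
    temp_offset_spread: float = 4.0
    bio12_median: float = 1200.0
    bio12_log_sd: float = 0.4
    bio18_fraction_mean: float = 0.35  # mean share of annual rain in warm quarter

    def __post_init__(self) -> None:
        if not self.correlation_length_km > 0:
            raise ValueError("correlation_length_km must be positive")


def _random_field(rng: np.random.Generator, grid: GridSpec, corr_km: float) -> np.ndarray:
    """Zero-mean, unit-variance spatially autocorrelated Gaussian field."""
    z = rng.standard_normal(grid.shape)
    sigma = corr_km / grid.cell_size_km
    f = gaussian_filter(z, sigma=sigma, mode="reflect")
    f -= f.mean()
    sd = f.std()
    return f / sd if sd > 0 else f


def simulate_climate(
    grid: GridSpec, params: ClimateFieldParams | None = None, seed: int = 0
) -> ClimateStack:
    """Generate the six-layer current-climate stack.

    BIO5 and BIO6 are derived from BIO1 plus/minus strictly positive offsets so
    the temperature ordering holds by construction; BIO12 is lognormal around
    its median; BIO18 is a logistic fraction of BIO12.
    """
    p = params or ClimateFieldParams()
    rng = np.random.default_rng(seed)
    corr = p.correlation_length_km
    g = {k: _random_field(rng, grid, corr) for k in ("t", "iso", "off5", "off6", "pr", "frac")}

    bio1 = p.bio1_mean + p.bio1_spread * g["t"]
    off5 = np.clip(p.temp_offset_mean + p.temp_offset_spread * g["off5"], 0.5, None)
    off6 = np.clip(p.temp_offset_mean + p.temp_offset_spread * g["off6"], 0.5, None)
    bio12 = p.bio12_median * np.exp(p.bio12_log_sd * g["pr"])
    logit0 = np.log(p.bio18_fraction_mean / (1 - p.bio18_fraction_mean))
    frac = 1.0 / (1.0 + np.exp(-(logit0 + g["frac"])))
    layers = {
        "BIO1": bio1,
        "BIO3": p.bio3_mean + p.bio3_spread * g["iso"],
        "BIO5": bio1 + off5,
        "BIO6": bio1 - off6,
        "BIO12": bio12,
        "BIO18": bio12 * frac,
    }
    return ClimateStack(grid, "current", layers)


@dataclass
class ScenarioShift:
    """Deterministic climate deltas plus optional noise for a future scenario.

    ``additive`` and ``multiplicative`` map variable names to deltas/factors;
    ``noise_sd`` adds a spatially autocorrelated perturbation per listed
    variable.  With ``pa_mask``/``damping`` given, per-cell deltas inside
    protected cells are multiplied by ``damping`` (0 = fully stable PAs,
    1 = no stabilization), emulating the slower climate velocity observed
    inside protected land.
    """

    label: str = "future"
    additive: dict[str, float] = field(default_factory=dict)
    multiplicative: dict[str, float] = field(default_factory=dict)
    noise_sd: dict[str, float] = field(default_factory=dict)
    noise_correlation_km: float = 10.0

    def __post_init__(self) -> None:
        for d in (self.additive, self.multiplicative, self.noise_sd):
            for k in d:
                if k not in CLIMATE_VARS:
                    raise ValueError(f"shift names unknown variable {k!r}")


def rcp45_like_shift() -> ScenarioShift:
    """Default future scenario: moderate-warming deltas (+2.4 degC, drier)."""
    return ScenarioShift(
        label="future_rcp45",
        additive={"BIO1": 2.4, "BIO5": 2.8, "BIO6": 2.0, "BIO3": 1.0},
        multiplicative={"BIO12": 0.9, "BIO18": 0.85},
    )


def project_future_climate(
    current: ClimateStack,
    shift: ScenarioShift,
    seed: int = 0,
    pa_mask: np.ndarray | None = None,
    damping: float = 1.0,
) -> ClimateStack:
    """Apply a scenario shift to the current stack.

    The per-cell delta for each variable is ``(mult*x + add + noise) - x``;
    inside PA cells it is scaled by ``damping``.  Physical orderings are
    re-enforced after shifting.
    """
    if not 0.0 <= damping <= 1.0:
        raise ValueError("damping must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    grid = current.grid
    layers: dict[str, np.ndarray] = {}
    for name, cur in current.layers.items():
        target = cur * shift.multiplicative.get(name, 1.0) + shift.additive.get(name, 0.0)
        sd = shift.noise_sd.get(name, 0.0)
        if sd > 0:
            target = target + sd * _random_field(rng, grid, shift.noise_correlation_km)
        delta = target - cur
        if pa_mask is not None and damping < 1.0:
            delta = np.where(pa_mask, damping * delta, delta)
        layers[name] = cur + delta
    # restore physical orderings possibly broken by differential shifts
    if {"BIO1", "BIO5", "BIO6"} <= set(layers):
        layers["BIO5"] = np.maximum(layers["BIO5"], layers["BIO1"])
        layers["BIO6"] = np.minimum(layers["BIO6"], layers["BIO1"])
    if "BIO12" in layers:
        layers["BIO12"] = np.maximum(layers["BIO12"], 0.0)
    if {"BIO12", "BIO18"} <= set(layers):
        layers["BIO18"] = np.clip(layers["BIO18"], 0.0, layers["BIO12"])
    return ClimateStack(grid, shift.label, layers, current.nodata_mask.copy())


# ---------------------------------------------------------------------------
# virtual species

@dataclass
class VirtualSpeciesDef:
    """A species with a known product-of-Gaussians niche.

    ``niche`` maps variable name to ``(optimum, breadth sigma)``; suitability
    at environment ``x`` is ``prod_v exp(-(x_v - opt_v)^2 / (2 sigma_v^2))``,
    equal to 1 at the joint optimum.  Cells with suitability at or above
    ``presence_threshold`` form the true range.
    """

    species_id: str
    niche: dict[str, tuple[float, float]]
    presence_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not self.niche:
            raise ValueError("niche must use at least one variable")
        for v, (_, sig) in self.niche.items():
            if sig <= 0:
                raise ValueError(f"{self.species_id}: sigma for {v} must be positive")
        if not 0.0 < self.presence_threshold < 1.0:
            raise ValueError("presence_threshold must lie in (0, 1)")


def true_suitability(vsp: VirtualSpeciesDef, climate: ClimateStack) -> np.ndarray:
    """Ground-truth suitability raster in [0, 1]; masked cells are 0."""
    missing = set(vsp.niche) - set(climate.layers)
    if missing:
        raise ValueError(f"{vsp.species_id}: niche variables missing from stack: {missing}")
    log_s = np.zeros(climate.grid.shape)
    for v, (opt, sig) in vsp.niche.items():
        log_s -= (climate.layers[v] - opt) ** 2 / (2.0 * sig**2)
    s = np.exp(log_s)
    s[climate.nodata_mask] = 0.0
    return s


def true_range(vsp: VirtualSpeciesDef, climate: ClimateStack) -> np.ndarray:
    """Boolean true-range raster: suitability >= presence threshold."""
    return true_suitability(vsp, climate) >= vsp.presence_threshold


def sample_occurrences(
    species_id: str,
    suitability: np.ndarray,
    range_mask: np.ndarray,
    n: int,
    grid: GridSpec,
    effort: np.ndarray | None = None,
    seed: int = 0,
) -> OccurrenceSet:
    """Presence-only sampling with replacement from true-range cells.

    Cell draw probabilities are proportional to suitability times the effort
    raster (uniform if absent); point coordinates are uniform within the
    drawn cell; years are uniform in 1990-2022.  Duplicate cells are allowed
    (thinning is a downstream step).
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if effort is not None:
        effort = np.asarray(effort, float)
        if effort.shape != grid.shape:
            raise ValueError("effort raster must share the grid")
        if np.any(effort < 0):
            raise ValueError("effort must be non-negative")
    w = np.where(range_mask, suitability, 0.0).astype(float)
    if effort is not None:
        w = w * effort
    total = w.sum()
    if total <= 0:
        raise UnsampleableSpeciesError(f"{species_id}: true range empty or zero weight")
    rng = np.random.default_rng(seed)
    flat = rng.choice(w.size, size=n, replace=True, p=(w / total).ravel())
    row, col = np.divmod(flat, grid.n_cols)
    x0, y0 = grid.origin
    s = grid.cell_size_km
    x = x0 + (col + rng.random(n)) * s
    y = y0 - (row + rng.random(n)) * s
    years = rng.integers(1990, 2023, size=n)
    return OccurrenceSet.from_points(species_id, x, y, year=years)


# ---------------------------------------------------------------------------
# protected areas

@dataclass
class PAMask:
    """Per-cell protected-area class raster (codes 0=none .. 7=VI)."""

    grid: GridSpec
    class_raster: np.ndarray

    def __post_init__(self) -> None:
        self.class_raster = np.asarray(self.class_raster, dtype=np.int8)
        if self.class_raster.shape != self.grid.shape:
            raise ValueError("class raster shape does not match grid")
        if self.class_raster.min() < 0 or self.class_raster.max() >= len(PA_CLASSES):
            raise ValueError("class codes out of range")

    def subset_mask(self, subset: str) -> np.ndarray:
        """Boolean raster of protected cells for ``subset`` 'strict' (I-IV) or 'all' (I-VI)."""
        if subset == "strict":
            codes = [PA_CODE[c] for c in STRICT_CLASSES]
        elif subset == "all":
            codes = [PA_CODE[c] for c in ALL_CLASSES]
        else:
            raise ValueError("subset must be 'strict' or 'all'")
        return np.isin(self.class_raster, codes)

    @property
    def strict_mask(self) -> np.ndarray:
        return self.subset_mask("strict")

    @property
    def all_mask(self) -> np.ndarray:
        return self.subset_mask("all")


def climate_stability_score(current: ClimateStack, future: ClimateStack) -> np.ndarray:
    """Per-cell mean normalized |delta| across variables (low = stable)."""
    score = np.zeros(current.grid.shape)
    for v in current.layers:
        d = np.abs(future.layers[v] - current.layers[v])
        denom = d.mean()
        score += d / denom if denom > 0 else d
    return score / len(current.layers)


_NEIGHBOURS = ((1, 0), (-1, 0), (0, 1), (0, -1))


def simulate_pa_network(
    grid: GridSpec,
    target_fraction: float,
    n_patches: int,
    class_mix: dict[str, float],
    placement: str = "uniform",
    seed: int = 0,
    climate_pair: tuple[ClimateStack, ClimateStack] | None = None,
    valid_mask: np.ndarray | None = None,
) -> PAMask:
    """Grow ``n_patches`` contiguous PA patches covering ~``target_fraction`` of cells.

    ``placement='uniform'`` seeds and grows patches at random;
    ``placement='stable-climate'`` (requires ``climate_pair=(current, future)``)
    seeds patches in the most climate-stable cells and grows them preferring
    stable cells.  Each patch gets one IUCN class drawn from ``class_mix``.
    """
    if not 0.0 < target_fraction < 1.0:
        raise ValueError("target_fraction must lie in (0, 1)")
    if abs(sum(class_mix.values()) - 1.0) > 1e-6:
        raise ValueError("class_mix must sum to 1")
    unknown = set(class_mix) - set(ALL_CLASSES)
    if unknown:
        raise ValueError(f"unknown PA classes in class_mix: {unknown}")
    valid = np.ones(grid.shape, bool) if valid_mask is None else valid_mask
    n_target = int(round(target_fraction * valid.sum()))
    if n_patches < 1 or n_patches > n_target:
        raise ValueError(
            f"target_fraction {target_fraction} infeasible for n_patches {n_patches}"
        )
    rng = np.random.default_rng(seed)

    if placement == "uniform":
        score = rng.random(grid.shape)
    elif placement == "stable-climate":
        if climate_pair is None:
            raise ValueError("stable-climate placement requires climate_pair")
        score = climate_stability_score(*climate_pair)
    else:
        raise ValueError("placement must be 'uniform' or 'stable-climate'")

    flat_valid = np.flatnonzero(valid.ravel())
    flat_score = score.ravel()
    # seed patches in the most favourable quintile of cells
    order = flat_valid[np.argsort(flat_score[flat_valid], kind="stable")]
    pool = order[: max(n_patches, len(order) // 5)]
    seeds = rng.choice(pool, size=n_patches, replace=False)

    patch_of = np.full(grid.n_cells, -1, dtype=np.int32)
    heap: list[tuple[float, float, int, int]] = []
    for pid, cell in enumerate(seeds):
        heapq.heappush(heap, (flat_score[cell], rng.random(), int(cell), pid))
    claimed = np.zeros(grid.n_cells, bool)
    claimed[seeds] = True
    n_assigned = 0
    ncols = grid.n_cols
    while heap and n_assigned < n_target:
        _, _, cell, pid = heapq.heappop(heap)
        patch_of[cell] = pid
        n_assigned += 1
        r, c = divmod(cell, ncols)
        for dr, dc in _NEIGHBOURS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < grid.n_rows and 0 <= cc < ncols:
                nb = rr * ncols + cc
                if not claimed[nb] and valid.ravel()[nb]:
                    claimed[nb] = True
                    heapq.heappush(heap, (flat_score[nb], rng.random(), nb, pid))

    # classes are allocated to patches against *area* quotas (largest patch
    # first, class with most remaining quota), so the realized protected area
    # honours class_mix even though grown patch sizes are unequal
    sizes = np.bincount(patch_of[patch_of >= 0], minlength=n_patches)
    quota = {c: class_mix[c] * n_assigned for c in class_mix}
    patch_codes = np.zeros(n_patches, dtype=np.int8)
    for pid in np.argsort(-sizes, kind="stable"):
        cls = max(quota, key=lambda c: quota[c])
        patch_codes[pid] = PA_CODE[cls]
        quota[cls] -= sizes[pid]
    out = np.zeros(grid.n_cells, dtype=np.int8)
    has_patch = patch_of >= 0
    out[has_patch] = patch_codes[patch_of[has_patch]]
    return PAMask(grid, out.reshape(grid.shape))


# ---------------------------------------------------------------------------
# spatial partitions

@dataclass
class PartitionRasters:
    """Zoogeographic-region and country labels for every cell."""

    grid: GridSpec
    region_id: np.ndarray
    country_id: np.ndarray

    def __post_init__(self) -> None:
        for name, arr in (("region_id", self.region_id), ("country_id", self.country_id)):
            if arr.shape != self.grid.shape:
                raise ValueError(f"{name} shape does not match grid")


def _grow_partition(grid: GridSpec, k: int, rng: np.random.Generator) -> np.ndarray:
    """Label every cell with one of k connected blobs (multi-source BFS)."""
    if k > grid.n_cells:
        raise ValueError(f"k={k} exceeds cell count {grid.n_cells}")
    labels = np.full(grid.n_cells, -1, dtype=np.int32)
    seeds = rng.choice(grid.n_cells, size=k, replace=False)
    frontier: deque[int] = deque()
    for i, cell in enumerate(seeds):
        labels[cell] = i
        frontier.append(int(cell))
    ncols = grid.n_cols
    while frontier:
        cell = frontier.popleft()
        r, c = divmod(cell, ncols)
        nbs = [(r + dr, c + dc) for dr, dc in _NEIGHBOURS]
        rng.shuffle(nbs)
        for rr, cc in nbs:
            if 0 <= rr < grid.n_rows and 0 <= cc < ncols:
                nb = rr * ncols + cc
                if labels[nb] < 0:
                    labels[nb] = labels[cell]
                    frontier.append(nb)
    return labels.reshape(grid.shape)


def simulate_partition(
    grid: GridSpec, k_regions: int, k_countries: int, seed: int = 0
) -> PartitionRasters:
    """Partition the grid into connected regions and countries."""
    if k_regions < 1 or k_countries < 1:
        raise ValueError("k_regions and k_countries must be at least 1")
    rng = np.random.default_rng(seed)
    regions = _grow_partition(grid, k_regions, rng)
    countries = _grow_partition(grid, k_countries, rng)
    return PartitionRasters(grid, regions, countries)
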