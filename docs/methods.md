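# Methods

## The model

The pipeline estimates, per species, a habitat-suitability function of six
bioclimatic predictors and converts it into binary range maps under a current
and a future climate scenario.  The statistical core is a weighted ensemble
of five presence/pseudo-absence classifiers:

- **GLM** — logistic regression on a full degree-2 polynomial response
  surface (linear, quadratic and pairwise-product terms).  The quadratic
  terms give the classic unimodal niche shape; the product terms keep the
  model well specified when a screened-out variable must be reconstructed
  from a linear combination of retained ones.
- **GBM** — gradient boosted trees (100 trees, depth 3, learning rate 0.1).
- **MaxEnt** — an L1-regularized logistic regression on the same degree-2
  feature expansion; the standard presence/background reduction of maximum
  entropy modelling.
- **RF** — random forest (100 trees, `min_samples_leaf=2`).
- **SVM** — RBF support vector classifier with Platt-scaled probabilities;
  default `C=10` (at `C=1` the boundary underfits curved niche contours).

Each algorithm is fit on 5 stratified 70/30 train/test splits; each
algorithm × replicate run is scored by test TSS (= sensitivity +
specificity − 1) and AUC.  Runs with TSS ≥ 0.7 are retained and pooled into
a single TSS-weighted average (at most 25 runs); per-algorithm averaging is
deliberately not used — the weights act on single runs.  The maxTSS
binarization threshold is computed on the pooled presence/pseudo-absence set
scored by the final ensemble (the evaluation split for this threshold is not
separately prescribed anywhere; the pooled set is the reproducible choice and
is logged).  The binarization rule is `suitability ≥ threshold → presence`,
with ties at the threshold counted as presence so tests can be bit-exact.

**No-dispersal projection.**  Amphibians and reptiles disperse poorly, so the
future range is the intersection of future-suitable cells with the current
range: no newly emerging habitat is ever occupied, future ⊆ current for
every species, and per-cell species loss is bounded in [0, 100] %.  A species
whose future intersection is empty is flagged extinct and excluded from
future-scenario denominators.

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| range-buffer filter | 400 | km | records farther from the expert range polygon are treated as errors; strictly-greater removal |
| thinning grain | 1 × 1 | km | one record per occupied cell, first in input order |
| minimum records | 5 | records | smaller samples are not modelable |
| calibration buffer | 500 | km | around presence cells, intersected with occupied regions |
| pseudo-absences | max(n_presence, 1000) | cells | uniform without replacement from the calibration background; unstated upstream, so explicit and configurable |
| train fraction / replicates | 0.7 / 5 | — | stratified splits |
| TSS retention | ≥ 0.7 | — | per algorithm × replicate run (a config switch can move the filter to algorithm means) |
| VIF threshold | < 10 | — | stepwise worst-first removal, computed per species on ≤ 10 000 sampled calibration cells |
| coverage benchmarks | > 15 %, > 30 % | — | strict inequalities |
| priority quantiles | top 20 % richness, bottom 20 % loss | — | inverse-empirical-CDF (type-1) quantiles, boundaries inclusive |

## The synthetic study system

The generator produces a world with known ground truth:

- **Climate.**  Each layer is a smoothed-noise Gaussian random field
  (configurable correlation length, default 10 km).  BIO5/BIO6 are derived
  as BIO1 ± strictly positive offsets (mean 10 °C, spread 4 °C), which
  enforces BIO6 ≤ BIO1 ≤ BIO5 by construction and gives inter-layer
  correlations of ≈ 0.9 — the magnitude real bioclim temperature layers
  show, and low enough that all six variables carry independent signal and
  pass the VIF < 10 screen, as the real six-variable set does.  BIO12 is
  lognormal (median 1200 mm, log-sd 0.4); BIO18 is a logistic fraction of
  BIO12 (mean 0.35), so 0 ≤ BIO18 ≤ BIO12 always.
- **Future scenario.**  A moderate-warming shift (+2.4 °C on BIO1, +2.8 /
  +2.0 °C on the extremes, −10 % annual and −15 % warm-quarter
  precipitation).  Optionally, per-cell deltas inside PA cells are multiplied
  by a damping factor (default 0.5), emulating the lower climate-change
  velocity observed inside protected land; physical orderings are re-enforced
  after shifting.
- **Virtual species.**  Suitability is a product of per-variable Gaussian
  responses; the true range is suitability ≥ 0.5.  Niche optima are drawn
  from the central quantiles (0.2–0.8) of the realized layers and breadths
  from 1.5–3 °C (BIO1) and 250–600 mm (BIO12); redraws guarantee at least 50
  range cells.  The 0.5 presence threshold keeps realized prevalence inside
  calibration areas near 10–20 %, which yields discrimination levels
  (test AUC ≈ 0.93, TSS ≈ 0.82) typical of published herpetofauna ensembles.
- **Sampling.**  Presence-only draws with replacement, cell probability ∝
  suitability × effort; an optional west-weighted effort raster emulates
  spatially biased collection.  Thinning happens downstream, as with real
  databases.
- **PAs.**  Contiguous patches grown by seeded flood-fill to a target
  protected fraction (default 0.15, 25 patches) with an IUCN class per patch;
  `stable-climate` placement seeds and grows patches in the cells with the
  smallest normalized climate deltas.
- **Partitions.**  Zoogeographic regions and countries are connected blobs
  from multi-source breadth-first growth.

**What the generator does not emulate:** coastlines and real geography,
distance-dependent spatial sampling artefacts (roads, rivers), niche shapes
that are skewed or multimodal, interactions between species, and land-use
change (held constant).  Passing tests therefore show that the pipeline
recovers known ranges and reproduces the PA mechanism *given* its modelling
assumptions — not that those assumptions hold for any particular real taxon.

## Numerical choices

- maxTSS threshold search is over the unique score values with integer
  confusion counts, so TSS ties are exact and the smallest maximizing
  threshold is returned deterministically.
- Decile/quantile classification uses the type-1 (inverted CDF) estimator;
  tied values fall into the lowest admissible bin.  Priority cells use the
  quantiles of the valid-cell distribution (cells with nonzero current
  richness); zero-richness cells can never be priorities because their loss
  is undefined.
- The Wilcoxon signed-rank test drops zero differences, uses average ranks
  for ties, and computes the exact two-sided p by dynamic programming over
  the (doubled) rank lattice for n ≤ 12; beyond that it uses the
  tie-corrected normal approximation with continuity correction.  The
  reported Z is the uncorrected normal deviate and flips sign when all
  differences are negated.  The worst-case gap between the exact p and the
  continuity-corrected approximation is 0.014 at n = 12 and falls below 0.01
  from n = 18.
- Inside/outside range-loss strata exclude species with zero current cells
  in the stratum (logged); the inside-vs-outside comparison is a paired
  signed-rank test (same species, two strata), while current-vs-future
  coverage uses the unpaired rank-sum variant because extinct species leave
  the future sample.
- VIF of a perfectly collinear variable is reported as a large finite cap
  (1e12), not an exception; stepwise ties break by the fixed variable order.
- Every stage seed is `sha256(master_seed : stage : species_id)` reduced
  below 2³¹, so adding species never perturbs existing species' results, and
  identical configs reproduce identical artifact checksums.

## Problem sizes

The canned validation studies use a 150 × 150 grid with 5 species × 5
replicate worlds (range recovery) and a 200 × 200 grid with 30 species (PA
mechanism); the toy end-to-end example uses 60 × 60 with 12 species.  These
sizes give stable medians while keeping a full run on one CPU in minutes;
all of them are configuration values, not limits.

## Known limitations

- Rasters are stored as single-band ESRI ASCII grids on an abstract planar
  equal-area grid; there is no CRS handling, reprojection or geodesic
  distance — real-world inputs must be pre-projected to an equal-area grid
  in km.
- The ensemble assigns zero suitability outside the calibration area rather
  than extrapolating.
- The rarity-weighted-richness aggregate is reported in both published
  two-step variants (`species_sum` and `cell_sum`); their magnitudes are not
  comparable to each other, so comparisons must fix one mode.
- With very few presences the pooled maxTSS threshold is noisy; the
  per-species threshold is logged so sensitivity checks are possible.
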