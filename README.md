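# sdmgap

Ensemble species distribution modelling and protected-area (PA) effectiveness
analysis on gridded landscapes — from occurrence cleaning through no-dispersal
future range projection to PA coverage metrics and conservation-gap mapping.

## Who this is for

Conservation biogeographers who want to ask, on a 1 km equal-area grid: *how
much of each species' suitable habitat falls inside protected areas today, how
does that change under a future climate, and where are the unprotected
priority areas?*  The package ships a complete synthetic study system
(virtual species with known niches on simulated climate), so every stage of
the pipeline can be run, tested and validated end-to-end with no downloads;
the same stage functions accept user-supplied rasters (ESRI ASCII grids) and
occurrence CSVs for real analyses.

## The method

1. **Occurrence preparation** — records are filtered to a 400 km buffer
   around the species' expert range polygon (when one exists), cleaned
   against a blacklist of problem coordinates, de-duplicated, thinned to one
   record per 1 km cell, and species with ≥ 5 thinned records are retained.
2. **Predictors** — six bioclimatic variables (BIO1, BIO3, BIO5, BIO6,
   BIO12, BIO18); future layers may be averaged across GCMs; per species,
   variables are screened by stepwise variance inflation factor
   (VIF = 1/(1−R²); iteratively drop the worst until all VIF < 10).
3. **Ensemble SDM** — per species: calibration area = occupied
   zoogeographic regions ∩ 500 km buffer around presences; random
   pseudo-absences (default `max(n_presence, 1000)`); 5 stratified 70/30
   train/test replicates × 5 algorithms (GLM, GBM, MaxEnt-style regularized
   logistic, RF, SVM); runs with test TSS ≥ 0.7 are pooled into a
   TSS-weighted ensemble `ŝ(x) = Σᵢ wᵢ pᵢ(x)`, `wᵢ = TSSᵢ/Σⱼ TSSⱼ`; the
   suitability map is binarized at the threshold maximizing
   TSS = sensitivity + specificity − 1.
4. **No-dispersal projection** — future range = future-suitable cells ∩
   current range; species with empty future ranges are flagged extinct.
5. **PA effectiveness** — per species and scenario: coverage fractions for
   strict (IUCN Ia–IV) and all (Ia–VI) PA subsets; % of species with any
   habitat in PAs; % above the >15% / >30% coverage benchmarks;
   rarity-weighted richness (score = 1/range size); range loss inside vs
   outside PAs, compared with Wilcoxon tests.
6. **Gap analysis** — cells in the top 20% of current richness and bottom
   20% of projected loss are conservation priorities; priority cells outside
   PAs are conservation gaps, summarized per country.

## Worked example

```python
from sdmgap import RunConfig, Pipeline

cfg = RunConfig.model_validate({
    "grid": {"n_rows": 60, "n_cols": 60},
    "species": {"n_species": 4, "n_occurrences": 400},
    "sdm": {"n_rep": 2},
    "seed": 1,
    "output_dir": "example_run",
})
pipe = Pipeline(cfg)
pipe.run()
print(pipe.species_status)
```

prints

```
{'sp000': 'ok', 'sp001': 'ok', 'sp002': 'ok', 'sp003': 'ok'}
```

meaning all four virtual species had enough records, at least one retained
model run, and a non-empty projected range.  `example_run/headline.json` then
holds the summary statistics, e.g.

```
{'pct_protected_strict_current': 100.0, 'pct_protected_strict_future': 75.0, ...}
```

— every species has suitable habitat inside a strict PA under current
climate, and 3 of the 4 surviving species still do under the future scenario.
`example_run/` also contains the per-species binary ranges
(`ranges/<scenario>/<species>.asc`), `metrics.csv` (one row per species ×
scenario with areas, coverages and losses), `tests.csv` (Wilcoxon
comparisons), the decile/priority/gap rasters under `gaps/`, and
`country_gaps.csv`.

The same pipeline is available from the shell:

```bash
sdmgap all --config config.yaml --seed 1 --out example_run
```

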