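"""End-to-end orchestration: synthetic world -> SDMs -> PA metrics -> gaps.

Stages (``simulate``, ``prep``, ``sdm``, ``assess``, ``gaps``) write their
artifacts under the configured output directory; a later stage either finds
its inputs in memory, reloads them from disk, or raises
:class:`DependencyError`.  A run manifest records the config hash, stage
seeds, per-file checksums, per-species statuses and warnings; identical
config + seed reproduces identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, stage_seed
from .effectiveness import (
    build_species_metrics,
    pct_species_protected,
    rarity_weighted_richness,
    summarize_group,
    wilcoxon_rank_sum,
    wilcoxon_signed_rank,
)
from .ensemble import BinaryRange, SDMSettings, fit_species_sdm
from .gaps import country_gap_summary, identify_priority_and_gaps, species_loss_map, richness_map
from .grid import GridSpec, read_ascii_grid, write_ascii_grid
from .landscape import (
    ClimateFieldParams,
    ClimateStack,
    PAMask,
    PartitionRasters,
    ScenarioShift,
    VirtualSpeciesDef,
    CLIMATE_VARS,
    project_future_climate,
    sample_occurrences,
    simulate_climate,
    simulate_pa_network,
    simulate_partition,
    true_range,
    true_suitability,
)
from .occurrences import (
    OccurrenceSet,
    clean_coordinates,
    cleaning_report,
    filter_by_range_buffer,
    filter_by_year,
    occupied_cells,
    select_modelable_species,
    thin_occurrences,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "prep", "sdm", "assess", "gaps")


class DependencyError(RuntimeError):
    """A stage was requested without its upstream artifacts."""


def generate_virtual_species(
    climate: ClimateStack, cfg, seed: int
) -> list[VirtualSpeciesDef]:
    """Draw a species roster with niches anchored in the realized climate.

    Optima are drawn from central quantiles of each niche variable's realized
    distribution and redrawn (up to 50 times) until the species' true range
    reaches the minimum viable size, so every simulated species exists.
    """
    rng = np.random.default_rng(seed)
    qlo, qhi = cfg.optimum_quantile_range
    out = []
    for i in range(cfg.n_species):
        sp = f"sp{i:03d}"
        for _ in range(50):
            niche = {}
            for var, (smin, smax) in cfg.niche_sigma.items():
                q = rng.uniform(qlo, qhi)
                opt = float(np.quantile(climate.layers[var][climate.valid_mask], q))
                niche[var] = (opt, float(rng.uniform(smin, smax)))
            vsp = VirtualSpeciesDef(sp, niche, cfg.presence_threshold)
            if true_range(vsp, climate).sum() >= cfg.min_range_cells:
                break
        out.append(vsp)
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class Pipeline:
    """Stateful runner holding in-memory artifacts between stages."""

    def __init__(self, config: RunConfig):
        self.cfg = config
        self.out = Path(config.output_dir)
        self.grid = GridSpec(
            config.grid.n_rows, config.grid.n_cols, config.grid.cell_size_km
        )
        self.warnings: list[str] = []
        self.species_status: dict[str, str] = {}
        self.stage_seeds: dict[str, int] = {}
        # artifacts
        self.stacks: dict[str, ClimateStack] | None = None
        self.pa: PAMask | None = None
        self.partition: PartitionRasters | None = None
        self.species: list[VirtualSpeciesDef] | None = None
        self.raw_occurrences: dict[str, OccurrenceSet] | None = None
        self.clean_occurrences: dict[str, OccurrenceSet] | None = None
        self.modelable: list[str] | None = None
        self.ranges: dict[str, dict[str, BinaryRange]] | None = None
        self.run_tables: list[pd.DataFrame] = []
        self.metrics: pd.DataFrame | None = None
        self.attributes: pd.DataFrame | None = None

    # -- helpers ----------------------------------------------------------
    def _seed(self, stage: str, extra: str = "") -> int:
        s = stage_seed(self.cfg.seed, stage, extra)
        self.stage_seeds[f"{stage}:{extra}" if extra else stage] = s
        return s

    def _write_raster(self, rel: str, data, fmt="%.8g") -> None:
        write_ascii_grid(self.out / rel, self.grid, np.asarray(data, float), fmt=fmt)

    # -- stage: simulate --------------------------------------------------
    def run_simulate(self) -> None:
        cfg = self.cfg
        params = ClimateFieldParams(**cfg.climate.model_dump())
        current = simulate_climate(self.grid, params, seed=self._seed("climate"))
        shift = ScenarioShift(
            label=cfg.scenario.label,
            additive=cfg.scenario.additive,
            multiplicative=cfg.scenario.multiplicative,
            noise_sd=cfg.scenario.noise_sd,
        )
        # provisional (undamped) future only to locate climate-stable cells
        provisional = project_future_climate(current, shift, seed=self._seed("future"))
        self.pa = simulate_pa_network(
            self.grid,
            cfg.pa.target_fraction,
            cfg.pa.n_patches,
            cfg.pa.class_mix,
            placement=cfg.pa.placement,
            seed=self._seed("pa"),
            climate_pair=(current, provisional) if cfg.pa.placement == "stable-climate" else None,
        )
        future = project_future_climate(
            current,
            shift,
            seed=self._seed("future"),
            pa_mask=self.pa.all_mask,
            damping=cfg.scenario.pa_damping,
        )
        self.stacks = {"current": current, cfg.scenario.label: future}
        self.partition = simulate_partition(
            self.grid, cfg.partition.k_regions, cfg.partition.k_countries,
            seed=self._seed("partition"),
        )
        self.species = generate_virtual_species(
            current, cfg.species, seed=self._seed("species")
        )
        rng_attr = np.random.default_rng(self._seed("attributes"))
        self.attributes = pd.DataFrame(
            {
                "threatened": rng_attr.random(len(self.species))
                < cfg.species.threatened_fraction
            },
            index=[v.species_id for v in self.species],
        )
        effort = None
        if cfg.species.effort_bias == "westward":
            effort = np.tile(
                np.linspace(9, 1, self.grid.n_cols), (self.grid.n_rows, 1)
            )
        occ = {}
        for vsp in self.species:
            suit = true_suitability(vsp, current)
            occ[vsp.species_id] = sample_occurrences(
                vsp.species_id,
                suit,
                suit >= vsp.presence_threshold,
                cfg.species.n_occurrences,
                self.grid,
                effort=effort,
                seed=self._seed("occurrences", vsp.species_id),
            )
        self.raw_occurrences = occ

        # persist
        for lab, st in self.stacks.items():
            for var, arr in st.layers.items():
                self._write_raster(f"climate/{lab}/{var}.asc", arr)
        self._write_raster("pa_classes.asc", self.pa.class_raster, fmt="%d")
        self._write_raster("regions.asc", self.partition.region_id, fmt="%d")
        self._write_raster("countries.asc", self.partition.country_id, fmt="%d")
        pd.concat(
            [o.records.assign(species_id=o.species_id) for o in occ.values()]
        ).to_csv(self.out / "occurrences_raw.csv", index=False)
        defs = {
            v.species_id: {
                "niche": {k: list(t) for k, t in v.niche.items()},
                "presence_threshold": v.presence_threshold,
            }
            for v in self.species
        }
        (self.out / "species_defs.json").write_text(json.dumps(defs, indent=1))
        self.attributes.to_csv(self.out / "species_attributes.csv")

    def _load_simulate(self) -> None:
        try:
            stacks: dict[str, ClimateStack] = {}
            for scen_dir in sorted((self.out / "climate").iterdir()):
                layers = {}
                for var in CLIMATE_VARS:
                    _, data, _ = read_ascii_grid(scen_dir / f"{var}.asc")
                    layers[var] = data
                stacks[scen_dir.name] = ClimateStack(self.grid, scen_dir.name, layers)
            self.stacks = stacks
            _, pa_classes, _ = read_ascii_grid(self.out / "pa_classes.asc")
            self.pa = PAMask(self.grid, pa_classes.astype(np.int8))
            _, regions, _ = read_ascii_grid(self.out / "regions.asc")
            _, countries, _ = read_ascii_grid(self.out / "countries.asc")
            self.partition = PartitionRasters(
                self.grid, regions.astype(np.int32), countries.astype(np.int32)
            )
            df = pd.read_csv(self.out / "occurrences_raw.csv")
            self.raw_occurrences = {
                sp: OccurrenceSet(sp, g.drop(columns="species_id"))
                for sp, g in df.groupby("species_id")
            }
            defs = json.loads((self.out / "species_defs.json").read_text())
            self.species = [
                VirtualSpeciesDef(
                    sp, {k: tuple(v) for k, v in d["niche"].items()},
                    d["presence_threshold"],
                )
                for sp, d in defs.items()
            ]
            self.attributes = pd.read_csv(
                self.out / "species_attributes.csv", index_col=0
            )
        except FileNotFoundError as e:
            raise DependencyError(f"missing simulate artifacts: {e}") from e

    # -- stage: prep ------------------------------------------------------
    def run_prep(self) -> None:
        if self.raw_occurrences is None:
            self._load_simulate()
        cfg = self.cfg.prep
        stages: dict[str, dict[str, OccurrenceSet]] = {
            "input": self.raw_occurrences, "buffer": {}, "clean": {}, "thin": {}
        }
        for sp, occ in self.raw_occurrences.items():
            o = filter_by_range_buffer(occ, None, cfg.buffer_km)
            stages["buffer"][sp] = o
            o = filter_by_year(o, cfg.min_year, cfg.max_year)
            o = clean_coordinates(o, blacklist=None, dedup=True)
            stages["clean"][sp] = o
            o = thin_occurrences(o, self.grid)
            stages["thin"][sp] = o
        self.clean_occurrences = stages["thin"]
        self.modelable = select_modelable_species(self.clean_occurrences, cfg.min_records)
        for sp in self.raw_occurrences:
            if sp not in self.modelable:
                self.species_status[sp] = "dropped_too_few_records"
        report = cleaning_report(stages, cfg.min_records)
        report.to_csv(self.out / "cleaning_report.csv", index=False)
        pd.concat(
            [o.records.assign(species_id=o.species_id)
             for o in self.clean_occurrences.values()]
        ).to_csv(self.out / "occurrences_clean.csv", index=False)

    def _load_prep(self) -> None:
        if self.raw_occurrences is None:
            self._load_simulate()
        try:
            df = pd.read_csv(self.out / "occurrences_clean.csv")
        except FileNotFoundError as e:
            raise DependencyError(f"missing prep artifacts: {e}") from e
        self.clean_occurrences = {
            sp: OccurrenceSet(sp, g.drop(columns="species_id"))
            for sp, g in df.groupby("species_id")
        }
        self.modelable = select_modelable_species(
            self.clean_occurrences, self.cfg.prep.min_records
        )

    # -- stage: sdm -------------------------------------------------------
    def run_sdm(self) -> None:
        if self.clean_occurrences is None:
            self._load_prep()
        settings = SDMSettings(
            algorithms=self.cfg.sdm.algorithms,
            learner_params=self.cfg.sdm.learner_params,
            n_pseudo_absence=self.cfg.sdm.n_pseudo_absence,
            retention_min=self.cfg.sdm.retention_min,
            train_frac=self.cfg.sdm.train_frac,
            n_rep=self.cfg.sdm.n_rep,
            calibration_buffer_km=self.cfg.sdm.calibration_buffer_km,
            vif_threshold=self.cfg.sdm.vif_threshold,
            vif_sample_cells=self.cfg.sdm.vif_sample_cells,
        )
        labels = list(self.stacks)
        ranges: dict[str, dict[str, BinaryRange]] = {lab: {} for lab in labels}
        self.run_tables = []
        var_rows = []
        for sp in self.modelable:
            presence = occupied_cells(self.clean_occurrences[sp], self.grid)
            res = fit_species_sdm(
                sp, presence, self.stacks, self.partition, settings,
                seed=self._seed("sdm", sp),
            )
            self.run_tables.append(res.runs)
            var_rows.append(
                {
                    "species_id": sp,
                    "kept_variables": " ".join(res.kept_variables),
                    "removal_order": " ".join(res.vif_removed),
                    "final_vifs": " ".join(
                        f"{v}:{res.final_vifs[v]:.3f}" for v in res.kept_variables
                    ),
                }
            )
            if res.status != "ok":
                self.species_status[sp] = "unmodelable"
                continue
            self.species_status[sp] = "ok"
            for lab in labels:
                r = res.ranges[lab]
                ranges[lab][sp] = r
                if r.extinct and lab != "current":
                    self.species_status[sp] = f"extinct:{lab}"
                self._write_raster(
                    f"ranges/{lab}/{sp}.asc", r.mask.astype(int), fmt="%d"
                )
        self.ranges = ranges
        pd.DataFrame(var_rows).to_csv(self.out / "variable_selection.csv", index=False)
        pd.concat(self.run_tables).to_csv(self.out / "model_runs.csv", index=False)
        (self.out / "species_status.json").write_text(
            json.dumps(self.species_status, indent=1)
        )

    def _load_sdm(self) -> None:
        if self.clean_occurrences is None:
            self._load_prep()
        rdir = self.out / "ranges"
        if not rdir.exists():
            raise DependencyError("missing sdm artifacts (ranges/)")
        ranges: dict[str, dict[str, BinaryRange]] = {}
        for scen_dir in sorted(rdir.iterdir()):
            ranges[scen_dir.name] = {}
            for f in sorted(scen_dir.glob("*.asc")):
                _, data, _ = read_ascii_grid(f)
                ranges[scen_dir.name][f.stem] = BinaryRange(
                    f.stem, scen_dir.name, data.astype(bool), np.nan
                )
        self.ranges = ranges
        self.species_status = json.loads(
            (self.out / "species_status.json").read_text()
        )

    # -- stage: assess ----------------------------------------------------
    def run_assess(self) -> None:
        if self.ranges is None:
            self._load_sdm()
        cfg = self.cfg.analysis
        future_label = next(l for l in self.ranges if l != "current")
        metrics = build_species_metrics(
            self.ranges, self.pa, self.partition, attributes=self.attributes
        )
        self.metrics = metrics
        metrics.drop(columns=["regions"], errors="ignore").to_csv(
            self.out / "metrics.csv", index=False
        )
        summaries = []
        for subset in ("strict", "all"):
            for grp in (None, "small_range", "threatened", "region"):
                s = summarize_group(metrics, grp, cfg.benchmarks, subset)
                s.insert(0, "subset", subset)
                s.insert(1, "group_by", grp or "global")
                summaries.append(s)
        pd.concat(summaries).to_csv(self.out / "summaries.csv", index=False)

        tests = []
        cur = metrics[metrics["scenario"] == "current"].set_index("species_id")
        fut = metrics[metrics["scenario"] == future_label].set_index("species_id")
        for subset in ("strict", "all"):
            li = fut[f"loss_inside_{subset}_pct"]
            lo = fut[f"loss_outside_{subset}_pct"]
            both = li.notna() & lo.notna()
            if both.sum() >= 2 and (li[both] != lo[both]).any():
                w = wilcoxon_signed_rank(lo[both].to_numpy(), li[both].to_numpy())
                tests.append(
                    {"comparison": f"loss_outside_vs_inside_{subset}", "n": w.n_used,
                     "statistic": w.statistic, "Z": w.z, "p": w.p, "paired": True}
                )
            cov_c = cur.loc[~cur["extinct"], f"coverage_{subset}"].dropna()
            cov_f = fut.loc[~fut["extinct"], f"coverage_{subset}"].dropna()
            if len(cov_c) >= 2 and len(cov_f) >= 2:
                w = wilcoxon_rank_sum(cov_c.to_numpy(), cov_f.to_numpy())
                tests.append(
                    {"comparison": f"coverage_current_vs_future_{subset}",
                     "n": w.n_used, "statistic": w.statistic, "Z": w.z, "p": w.p,
                     "paired": False}
                )
        pd.DataFrame(tests).to_csv(self.out / "tests.csv", index=False)

        headline = {}
        for subset in ("strict", "all"):
            for lab in self.ranges:
                key = "current" if lab == "current" else "future"
                try:
                    headline[f"pct_protected_{subset}_{key}"] = pct_species_protected(
                        self.ranges[lab], self.pa, subset
                    )
                except ValueError:
                    headline[f"pct_protected_{subset}_{key}"] = None
                headline[f"rwr_{subset}_{key}"] = rarity_weighted_richness(
                    self.ranges[lab], self.pa, subset, "species_sum"
                )
        (self.out / "headline.json").write_text(json.dumps(headline, indent=1))

    # -- stage: gaps ------------------------------------------------------
    def run_gaps(self) -> None:
        if self.ranges is None:
            self._load_sdm()
        cfg = self.cfg.analysis
        future_label = next(l for l in self.ranges if l != "current")
        rich = richness_map(self.ranges["current"], self.grid)
        loss = species_loss_map(
            self.ranges["current"], self.ranges[future_label], self.grid
        )
        pm = identify_priority_and_gaps(
            rich.astype(float), loss, self.pa, cfg.pa_subset,
            cfg.top_frac, cfg.bottom_frac,
        )
        self._write_raster("gaps/richness.asc", rich, fmt="%d")
        self._write_raster("gaps/loss_pct.asc", np.where(np.isfinite(loss), loss, -9999.0))
        self._write_raster("gaps/richness_decile.asc", pm.richness_bin, fmt="%d")
        self._write_raster("gaps/loss_decile.asc", pm.loss_bin, fmt="%d")
        self._write_raster("gaps/priority.asc", pm.priority.astype(int), fmt="%d")
        self._write_raster("gaps/gap.asc", pm.gap.astype(int), fmt="%d")
        country_gap_summary(pm.gap, self.partition).to_csv(
            self.out / "country_gaps.csv", index=False
        )
        self.priority_map = pm

    # -- orchestration ----------------------------------------------------
    def run(self, stages: list[str] | None = None) -> dict:
        stages = list(stages) if stages else list(STAGES)
        unknown = set(stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")
        self.out.mkdir(parents=True, exist_ok=True)
        for st in STAGES:
            if st in stages:
                getattr(self, f"run_{st}")()
        manifest = {
            "config_hash": self.cfg.config_hash(),
            "version": __version__,
            "stages_run": stages,
            "stage_seeds": self.stage_seeds,
            "species_status": self.species_status,
            "warnings": self.warnings,
            "checksums": {
                str(p.relative_to(self.out)): _sha256(p)
                for p in sorted(self.out.rglob("*"))
                if p.is_file() and p.name != "manifest.json"
            },
        }
        (self.out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        return manifest


def run_pipeline(config: RunConfig, stages: list[str] | None = None) -> dict:
    """Validate-and-run convenience wrapper returning the manifest."""
    return Pipeline(config).run(stages)
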