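"""End-to-end pipeline: simulate/load -> prep -> indicators -> null model -> drivers.

One config drives every stage; all randomness flows from seeds recorded
in the run manifest together with per-stage record counts and runtimes,
so a run is fully reproducible and the filter bookkeeping (hauls, sites
and species surviving each step) is auditable.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import drivers, indicators, nullmodel, survey, synthetic, traitspace

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "validate_inputs"]

NATURAL_DRIVERS = [
    "depth_m", "sbt_winter", "sbt_seasonality", "salinity_winter",
    "salinity_variability", "pci", "substrate_richness", "substrate_evenness",
]
EFFORT_DRIVERS = ["beam_effort", "otter_effort"]


@dataclass
class PipelineConfig:
    out_dir: str = "trawldiv_run"
    # input CSVs; when hauls is None the synthetic generator provides them
    hauls: str | None = None
    traits: str | None = None
    lw_params: str | None = None
    covariates: str | None = None
    agg_map: str | None = None
    # synthetic scenario
    n_species: int = 77
    n_sites: int = 119
    n_years: int = 32
    process: str = "neutral"
    strength: float = 0.0
    mean_hauls: float = 2.0
    # filters
    min_duration: float = 27.0
    max_duration: float = 33.0
    min_depth: float = 20.0
    site_coverage: float = 26 / 32
    species_occurrence: float = 7 / 32
    # trait space
    correction: str = "sqrt"
    m_max: int = 4
    log_continuous: bool = True
    # null model
    n_perm: int = 199
    presence_mode: str = "union"
    # drivers
    profile: str = "natural"
    # seeds
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.profile not in ("natural", "all"):
            raise ValueError("profile must be 'natural' or 'all'")
        if self.presence_mode not in ("union", "year"):
            raise ValueError("presence_mode must be 'union' or 'year'")
        for key in ("hauls", "traits", "lw_params", "covariates", "agg_map"):
            path = getattr(self, key)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"config path {key}={path!r} does not exist")
        if self.hauls is not None and (self.traits is None or self.lw_params is None):
            raise ValueError("supplied haul data requires traits and lw_params paths")


def validate_inputs(community_species, traits: pd.DataFrame) -> list[dict]:
    """Report structural problems in the trait table vs community species.

    Findings are dicts with ``severity`` ("fatal" or "warning") and
    ``message``; the pipeline treats fatal findings as errors.
    """
    findings: list[dict] = []
    for sp in community_species:
        if sp not in traits.index:
            findings.append(
                {"severity": "fatal", "message": f"species {sp!r} missing from trait table"}
            )
    for col in traits.columns:
        n_missing = int(traits[col].isna().sum())
        if n_missing:
            findings.append(
                {"severity": "fatal", "message": f"trait {col!r} has {n_missing} missing values"}
            )
    for col, levels in synthetic.TRAIT_LEVELS.items():
        if col in traits.columns:
            bad = sorted(set(traits[col].dropna()) - set(levels))
            if bad:
                findings.append(
                    {"severity": "warning", "message": f"trait {col!r} has unknown levels: {bad}"}
                )
    return findings


def _stage(manifest: dict, name: str, start: float, **counts) -> None:
    manifest["stages"].append(
        {"stage": name, "runtime_s": round(time.perf_counter() - start, 3), **counts}
    )


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and write artifacts + manifest to the out dir."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": []}
    rng_seed = int(config.seed)

    # --- inputs -----------------------------------------------------------
    t0 = time.perf_counter()
    if config.hauls is None:
        ss = np.random.SeedSequence(rng_seed)
        s_pool, s_sites, s_comm, s_hauls = [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(4)]
        pool = synthetic.generate_species_pool(config.n_species, seed=s_pool)
        sites = synthetic.generate_sites(config.n_sites, config.n_years, seed=s_sites)
        communities, truth = synthetic.assemble_communities(
            pool, sites, config.process, config.strength,
            synthetic.default_target_richness(config.n_species), seed=s_comm,
        )
        hauls = synthetic.generate_hauls(
            communities, sites, pool, {"mean_hauls": config.mean_hauls}, seed=s_hauls
        )
        traits = pool[synthetic.TRAIT_COLUMNS]
        lw = pool[["lw_a", "lw_b"]].rename(columns={"lw_a": "a", "lw_b": "b"}).reset_index()
        covariates = sites.drop(columns=["env"])
        agg_map: dict[str, str] = {}
        hauls.to_csv(out / "hauls.csv", index=False)
        traits.to_csv(out / "traits.csv")
        lw.to_csv(out / "lw_params.csv", index=False)
        covariates.to_csv(out / "covariates.csv")
        truth.to_csv(out / "truth.csv", index=False)
    else:
        hauls = pd.read_csv(config.hauls)
        traits = pd.read_csv(config.traits, index_col=0)
        lw = pd.read_csv(config.lw_params)
        covariates = pd.read_csv(config.covariates, index_col=0) if config.covariates else None
        agg_map = {}
        if config.agg_map:
            m = pd.read_csv(config.agg_map)
            agg_map = dict(zip(m["species"], m["group"]))
    _stage(manifest, "inputs", t0, n_haul_records=len(hauls), n_species_pool=len(traits))

    findings = validate_inputs(hauls["species"].unique(), traits)
    fatal = [f for f in findings if f["severity"] == "fatal"]
    if fatal:
        raise ValueError("input validation failed: " + "; ".join(f["message"] for f in fatal))

    # --- survey prep ------------------------------------------------------
    t0 = time.perf_counter()
    filtered = survey.filter_hauls(hauls, config.min_duration, config.max_duration, config.min_depth)
    kept_sites = survey.filter_sites_by_coverage(filtered, config.site_coverage)
    filtered = filtered[filtered["site_id"].isin(kept_sites)]
    if agg_map:
        filtered = survey.aggregate_species(filtered, agg_map)
    biomass_records = survey.cpue_to_biomass(filtered, lw)
    community = survey.build_community_matrix(biomass_records)
    community = survey.filter_species_by_occurrence(community, config.species_occurrence)
    _stage(
        manifest, "survey_prep", t0,
        n_hauls=int(filtered["haul_id"].nunique()),
        n_sites=len(kept_sites),
        n_species=len(community.species),
        n_site_years=len(community.biomass),
    )

    # --- trait space + indicators ----------------------------------------
    t0 = time.perf_counter()
    traits_used = traits.loc[community.species]
    space = traitspace.build_trait_space(
        traits_used,
        correction=config.correction,
        log_continuous=config.log_continuous,
        m_max=config.m_max,
        community_richness=community.richness(),
    )
    table = indicators.compute_indicator_table(community, space)
    if len(table) >= 20:
        table = indicators.effort_standardize(table)
    table.to_csv(out / "indicators.csv", index=False)
    _stage(manifest, "indicators", t0, m_axes=space.m, n_records=len(table))

    # --- null model -------------------------------------------------------
    t0 = time.perf_counter()
    if config.presence_mode == "union":
        presence = community.presence("union")
    else:  # single-year layer: most recent year with data
        last = community.years.max()
        presence = community.presence("year").xs(last, level="year")
    null = nullmodel.null_distribution(presence, space, config.n_perm, seed=rng_seed + 1)
    null.table.to_csv(out / "null_results.csv", index=False)
    _stage(manifest, "null_model", t0, n_perm=config.n_perm, n_sites=len(null.sites))

    # --- trends -----------------------------------------------------------
    t0 = time.perf_counter()
    trend_rows = []
    for col in ("SRic", "SEve", "TRic", "TEve"):
        annual = table.groupby("year")[col].mean().dropna()
        if len(annual) >= 8:
            tr = drivers.temporal_trend(annual)
            trend_rows.append(
                {"indicator": col, "slope": tr.slope, "p_value": tr.p_value,
                 "f_stat": tr.f_stat, "deviance_explained": tr.deviance_explained,
                 "lag1_autocorr": tr.lag1_autocorr}
            )
        per_site = drivers.per_site_trend(table, col)
        per_site.insert(0, "indicator", col)
        per_site.to_csv(out / f"trends_per_site_{col}.csv", index=False)
    if trend_rows:
        pd.DataFrame(trend_rows).to_csv(out / "trends_global.csv", index=False)
    _stage(manifest, "trends", t0, n_indicators=4)

    # --- drivers ----------------------------------------------------------
    t0 = time.perf_counter()
    if covariates is not None:
        cand_names = NATURAL_DRIVERS + (EFFORT_DRIVERS if config.profile == "all" else [])
        cand_names = [c for c in cand_names if c in covariates.columns]
        site_means = table.groupby("site_id")[["SRic", "SEve", "TRic", "TEve"]].mean()
        x = covariates.loc[site_means.index, cand_names]
        rvi_rows, model_rows = [], []
        for col in site_means.columns:
            y = site_means[col].dropna()
            if len(y) < 3 * len(cand_names) + 3:
                logger.info("skipping RVI for %s: too few sites", col)
                continue
            res = drivers.all_subsets_rvi(y.to_numpy(), x.loc[y.index])
            frame = res.to_frame()
            frame.insert(0, "indicator", col)
            rvi_rows.append(frame)
            models = res.model_table.copy()
            models["covariates"] = models["covariates"].map(lambda s: "+".join(s) or "(intercept)")
            models.insert(0, "indicator", col)
            model_rows.append(models)
        if rvi_rows:
            pd.concat(rvi_rows).to_csv(out / "rvi.csv", index=False)
            pd.concat(model_rows).to_csv(out / "rvi_models.csv", index=False)
    _stage(manifest, "drivers", t0)

    manifest["seed"] = rng_seed
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
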