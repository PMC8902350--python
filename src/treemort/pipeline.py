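"""End-to-end analysis orchestration.

One run covers, for each focal stage (sapling / juvenile / adult) and
each stratification scheme:

    pooled      DBH + CON + HET + environment
    stratified  DBH + the stage-admissible Ea/Sa/La CON and HET strata
                + environment

The steps are: read and validate the census; classify stages; select
focal species (>= 50 per stage) and exclude the 25 m edge band as
focals; per-grid stage mortality with pairwise signed-rank tests; per
life form, select the neighborhood radius by lowest AIC of the pooled
CON+HET model over 5-40 m; assemble standardized covariates (natural-log
DBH, neighborhood strata at the selected radius, per-quadrat terrain and
soil); exhaustively average binomial mixed models by AIC weight.  All
outputs are CSV/JSON, listed in a manifest with content hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .census import PlotGeometry, exclude_edge, read_census, select_focal_species
from .model_average import AICModelAverager, select_radius, DEFAULT_RADII
from .mortality import pairwise_stage_tests, stage_mortality_summary
from .neighborhood import stratified_indices
from .stages import STAGES, admissible_relative_stages
from .terrain import derive_environment

log = logging.getLogger(__name__)

ENV_VARS = ("ELEV", "SLOP", "ASPE", "CONV", "TN", "TP", "pH", "SMC")
_ENV_COLUMN = {
    "ELEV": "elev", "SLOP": "slop", "ASPE": "aspe", "CONV": "conv",
    "TN": "tn", "TP": "tp", "pH": "ph", "SMC": "smc",
}
_REL_PREFIX = {"earlier": "Ea", "same": "Sa", "later": "La"}


@dataclass
class RunConfig:
    census: str | None = None
    altimetry: str | None = None
    soil: str | None = None
    environment: str | None = None  # precomputed per-quadrat table
    out_dir: str = "results"
    width: float = 500.0
    height: float = 400.0
    edge_buffer: float = 25.0
    min_per_stage: int = 50
    radii: tuple = DEFAULT_RADII
    delta_aic: float = 2.0
    averaging: str = "natural"
    env_vars: tuple = ENV_VARS
    schemes: tuple = ("pooled", "stratified")
    seed: int = 0
    guard: int = 16

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        cfg = cls(**known)
        return cfg

    @property
    def geometry(self) -> PlotGeometry:
        return PlotGeometry(
            width=self.width, height=self.height, edge_buffer=self.edge_buffer
        )


def candidate_variables(stage: str, scheme: str, env_vars=ENV_VARS) -> list[str]:
    """The candidate covariate list for one stage analysis."""
    if scheme == "pooled":
        ni = ["CON", "HET"]
    elif scheme == "stratified":
        ni = []
        for rel in admissible_relative_stages(stage):
            ni.append(f"{_REL_PREFIX[rel]}CON")
        for rel in admissible_relative_stages(stage):
            ni.append(f"{_REL_PREFIX[rel]}HET")
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return ["DBH"] + ni + list(env_vars)


def assemble_covariates(
    focal: pd.DataFrame, ni: pd.DataFrame, env: pd.DataFrame, variables: list[str]
) -> pd.DataFrame:
    """Raw (unstandardized) covariate frame for a focal sample."""
    cov = pd.DataFrame(index=focal.index)
    for v in variables:
        if v == "DBH":
            cov[v] = np.log(focal["dbh"].to_numpy())
        elif v in ni.columns:
            cov[v] = ni.loc[focal.index, v].to_numpy()
        elif v in _ENV_COLUMN:
            cov[v] = env.reindex(focal["quadrat_id"].to_numpy())[_ENV_COLUMN[v]].to_numpy()
        else:
            raise KeyError(f"covariate {v} not available")
    return cov


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_analysis(
    config: RunConfig,
    census: pd.DataFrame | None = None,
    environment: pd.DataFrame | None = None,
) -> dict:
    """Run the full pipeline; returns the result bundle and writes files.

    ``census`` and ``environment`` may be passed in-memory (e.g. from the
    synthetic generator); otherwise they are read / derived from the
    configured paths.
    """
    geom = config.geometry
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save(df: pd.DataFrame, name: str):
        p = out_dir / name
        df.to_csv(p, index=False)
        written.append(p)

    if census is None:
        if config.census is None:
            raise ValueError("no census provided")
        census, rejects = read_census(config.census, geom)
        if len(rejects):
            save(rejects, "census_rejects.csv")

    if environment is None:
        if config.environment:
            environment = pd.read_csv(config.environment).set_index(
                "quadrat_id", drop=False
            )
        elif config.altimetry:
            soil = pd.read_csv(config.soil) if config.soil else None
            environment = derive_environment(
                pd.read_csv(config.altimetry), soil, geom
            )
        else:
            raise ValueError("no environment source provided")

    focal_species = select_focal_species(census, config.min_per_stage)
    interior = exclude_edge(census, geom)
    focal_all = interior[interior["species"].isin(focal_species)]
    log.info(
        "%d focal species, %d focal stems (of %d)",
        len(focal_species), len(focal_all), len(census),
    )
    if focal_all.empty:
        raise RuntimeError("stage 'focal selection': no focal trees remain")

    bundle: dict = {
        "focal_species": focal_species,
        "n_focal": len(focal_all),
        "n_census": len(census),
    }

    # Fig.2-equivalent mortality tables
    mort = stage_mortality_summary(focal_all)
    tests = pairwise_stage_tests(focal_all)
    save(mort, "stage_mortality.csv")
    save(tests, "stage_mortality_tests.csv")
    bundle["stage_mortality"] = mort
    bundle["stage_tests"] = tests

    # per life form: optimal radius from the pooled CON+HET model
    radii = tuple(config.radii)
    ni_all = stratified_indices(census, focal_all, radii=radii)
    best_radius: dict[str, float] = {}
    curves = []
    for form in sorted(focal_all["life_form"].unique()):
        sub = focal_all[focal_all["life_form"] == form]
        ni_sub = ni_all.loc[(slice(None), sub.index), :]
        sel = select_radius(
            ni_sub,
            sub["dead"].to_numpy(),
            sub["species"].to_numpy(),
            sub["grid_id"].to_numpy(),
            radii=radii,
        )
        best_radius[form] = sel.radius
        c = sel.aic_curve.assign(life_form=form)
        curves.append(c)
    save(pd.concat(curves, ignore_index=True), "radius_aic_curves.csv")
    bundle["optimal_radius"] = best_radius

    # NI at each stem's life-form radius
    ni_opt = pd.concat(
        [
            ni_all.xs(best_radius[form], level="radius_key").loc[
                focal_all.index[focal_all["life_form"] == form]
            ]
            for form in best_radius
        ]
    ).loc[focal_all.index]

    results: dict = {}
    dropped: dict = {}
    n_models: dict = {}
    for stage in STAGES:
        focal = focal_all[focal_all["stage"] == stage]
        if focal.empty:
            log.warning("no focal trees in stage %s; skipped", stage)
            continue
        for scheme in config.schemes:
            variables = candidate_variables(stage, scheme, config.env_vars)
            try:
                cov = assemble_covariates(focal, ni_opt, environment, variables)
                est = AICModelAverager(
                    delta=config.delta_aic, mode=config.averaging, guard=config.guard
                )
                est.fit(
                    cov,
                    focal["dead"].to_numpy(),
                    species=focal["species"].to_numpy(),
                    grid=focal["grid_id"].to_numpy(),
                )
            except Exception as exc:
                raise RuntimeError(f"stage '{stage}/{scheme}' failed: {exc}") from exc
            key = f"{stage}_{scheme}"
            results[key] = est.results_
            dropped[key] = est.n_dropped_
            n_models[key] = len(est.models_)
            save(est.results_.reset_index(), f"estimates_{key}.csv")
    bundle["estimates"] = results

    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "seed": config.seed,
        "optimal_radius": best_radius,
        "models_fitted": n_models,
        "dropped_models": dropped,
        "outputs": {p.name: _sha256(p) for p in written},
    }
    mpath = out_dir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1, default=str))
    bundle["manifest"] = manifest
    return bundle
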