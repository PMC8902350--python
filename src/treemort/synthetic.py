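"""Synthetic stem-mapped plots with known mortality ground truth.

The generator emulates the broad features of a subtropical forest
dynamics plot so that every stage of the analysis pipeline is testable
end to end:

* per-species clustered point patterns from a Thomas process (Poisson
  parents, Gaussian-scattered offspring) — a standard proxy for
  dispersal limitation;
* a reverse-J stem-size distribution: DBH = 1 cm + exponential, whose
  default rate 0.215 / cm gives a mean DBH of about 5.65 cm with the
  majority of stems under 4 cm;
* smooth environmental surfaces (elevation and four soil properties)
  from Gaussian-filtered noise on the 5 m corner lattice, run through
  the same terrain derivations the analysis uses;
* census-2 fates drawn from the same binomial mixed-logit the analysis
  fits: logit p = alpha + sum beta_v z_v + u_species + u_grid, with the
  neighborhood-index covariates computed by the neighborhood module at
  the configured generating radius.

The truth coefficients are per-SD: stage-admissible strata are
standardized within stage groups and other covariates globally, with
scaling moments taken from interior stems (the ones a downstream
analysis keeps as focals), so signs and significance survive the
analysis's own re-standardization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.interpolate import RegularGridInterpolator

from .census import PlotGeometry, add_cell_ids
from .neighborhood import stratified_indices
from .stages import LIFE_FORMS, classify_stages
from .terrain import environment_table

ENV_FIELD_DEFAULTS = {
    # mean, sd per surface (elevation m; TN/TP g/kg; pH; SMC fraction)
    "elevation": (450.0, 60.0),
    "tn": (2.0, 0.4),
    "tp": (0.45, 0.10),
    "ph": (4.7, 0.20),
    "smc": (0.30, 0.05),
}


@dataclass
class TruthParams:
    """Generating coefficients of the mortality model (per-SD scale).

    The default scenario mirrors the qualitative pattern the analysis is
    built to detect: later-stage conspecific crowding raises mortality,
    earlier-stage conspecific and later-stage heterospecific crowding
    lower it, and baseline mortality declines from sapling to adult
    (``stage_alpha``; set it to None for a single flat intercept).
    """

    alpha: float = -2.0
    stage_alpha: dict | None = field(
        default_factory=lambda: {"sapling": -2.0, "juvenile": -2.2, "adult": -2.45}
    )
    betas: dict = field(
        default_factory=lambda: {"LaCON": 0.3, "EaCON": -0.2, "LaHET": -0.2}
    )
    sigma_species: float = 0.5
    sigma_grid: float = 0.3
    radius: float = 15.0


@dataclass
class SyntheticConfig:
    """Study-scale defaults: a 500 x 400 m plot, 30 species in three life
    forms, roughly 80,000 stems, reverse-J sizes with mean DBH near 5.7 cm."""

    geometry: PlotGeometry = field(default_factory=PlotGeometry)
    n_species: int = 30
    life_form_mix: dict = field(
        default_factory=lambda: {"shrub": 0.4, "subtree": 0.3, "canopy": 0.3}
    )
    parents_per_species: float = 40.0
    offspring_per_parent: float = 68.0
    dispersal_sd: float = 15.0
    dbh_rate: float = 0.215
    env_length_scale: float = 40.0
    n_soil_samples: int = 1310
    truth: TruthParams = field(default_factory=TruthParams)
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.life_form_mix.values()) - 1.0) > 1e-9:
            raise ValueError("life_form_mix proportions must sum to 1")
        for v in (
            self.parents_per_species,
            self.offspring_per_parent,
            self.dispersal_sd,
            self.dbh_rate,
        ):
            if v <= 0:
                raise ValueError("intensities, dispersal sd and dbh rate must be > 0")


@dataclass
class SyntheticTruth:
    """Realized ground truth stored alongside a generated census."""

    alpha: float
    stage_alpha: dict | None
    betas: dict
    sigma_species: float
    sigma_grid: float
    radius: float
    u_species: dict
    u_grid: np.ndarray
    linpred: np.ndarray
    p_dead: np.ndarray

    def to_json(self) -> str:
        d = {
            "alpha": self.alpha,
            "stage_alpha": self.stage_alpha,
            "betas": self.betas,
            "sigma_species": self.sigma_species,
            "sigma_grid": self.sigma_grid,
            "radius": self.radius,
            "u_species": {k: float(v) for k, v in self.u_species.items()},
            "u_grid": [float(v) for v in self.u_grid],
        }
        return json.dumps(d, indent=1)


def _species_life_forms(config: SyntheticConfig) -> dict[str, str]:
    """Deterministic split of species codes among life forms by the mix."""
    n = config.n_species
    counts = {f: int(round(config.life_form_mix.get(f, 0.0) * n)) for f in LIFE_FORMS}
    while sum(counts.values()) < n:
        counts[LIFE_FORMS[0]] += 1
    while sum(counts.values()) > n:
        counts[max(counts, key=counts.get)] -= 1
    out = {}
    i = 0
    for f in LIFE_FORMS:
        for _ in range(counts[f]):
            out[f"sp{i:03d}"] = f
            i += 1
    return out


def _thomas_points(rng, geometry, n_parents_mean, offspring_mean, sd):
    """One species' stem coordinates from a Thomas cluster process.

    Offspring are wrapped on the plot torus so edge density stays uniform.
    """
    w, h = geometry.width, geometry.height
    n_par = rng.poisson(n_parents_mean)
    if n_par == 0:
        return np.empty((0, 2))
    parents = rng.uniform([0, 0], [w, h], size=(n_par, 2))
    n_off = rng.poisson(offspring_mean, size=n_par)
    centers = np.repeat(parents, n_off, axis=0)
    pts = centers + rng.normal(0.0, sd, size=centers.shape)
    pts[:, 0] %= w
    pts[:, 1] %= h
    return pts


def _smooth_field(rng, shape, length_scale_cells, mean, sd):
    raw = rng.standard_normal(shape)
    sm = gaussian_filter(raw, sigma=length_scale_cells, mode="reflect")
    sm = (sm - sm.mean()) / max(sm.std(), 1e-12)
    return mean + sd * sm


def generate_plot(
    config: SyntheticConfig | None = None, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate (census, environment table, truth).

    The census frame is in the validated dialect (dead flag, stage and
    cell ids attached); the environment table is per 5 m quadrat.  The
    same seed always yields the same outputs.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    geom = config.geometry

    # --- stems ------------------------------------------------------------
    life_forms = _species_life_forms(config)
    frames = []
    for sp, form in life_forms.items():
        pts = _thomas_points(
            rng, geom, config.parents_per_species, config.offspring_per_parent,
            config.dispersal_sd,
        )
        if not len(pts):
            continue
        frames.append(
            pd.DataFrame(
                {"species": sp, "life_form": form, "x": pts[:, 0], "y": pts[:, 1]}
            )
        )
    if not frames:
        raise ValueError("configuration produced zero trees")
    census = pd.concat(frames, ignore_index=True)
    n = len(census)
    census.insert(0, "tag", [f"t{i:06d}" for i in range(n)])
    census["dbh"] = 1.0 + rng.exponential(1.0 / config.dbh_rate, size=n)
    census["stage"] = classify_stages(census["life_form"], census["dbh"])
    census = add_cell_ids(census, geom)

    # --- environment ------------------------------------------------------
    shape = (geom.n_quadrat_y + 1, geom.n_quadrat_x + 1)
    ls = config.env_length_scale / geom.quadrat_cell
    corner_fields = {
        name: _smooth_field(rng, shape, ls, mean, sd)
        for name, (mean, sd) in ENV_FIELD_DEFAULTS.items()
    }
    env = environment_table(
        corner_fields["elevation"],
        geom,
        {k: corner_fields[k] for k in ("tn", "tp", "ph", "smc")},
    )

    # --- covariates and fates --------------------------------------------
    ni = stratified_indices(census, radius=config.truth.radius)
    cov = pd.DataFrame(index=census.index)
    cov["DBH"] = np.log(census["dbh"].to_numpy())
    for s in ("EaCON", "SaCON", "LaCON", "EaHET", "SaHET", "LaHET", "CON", "HET"):
        cov[s] = ni[s].to_numpy()
    envq = env.reindex(census["quadrat_id"].to_numpy())
    for c, name in (
        ("elev", "ELEV"), ("conv", "CONV"), ("slop", "SLOP"), ("aspe", "ASPE"),
        ("tn", "TN"), ("tp", "TP"), ("ph", "pH"), ("smc", "SMC"),
    ):
        cov[name] = envq[c].to_numpy()
    cov["CONV"] = cov["CONV"].fillna(0.0)  # boundary quadrats; excluded as focals

    # Stage-admissible strata (Ea*/Sa*/La*) mean different neighbor sets for
    # different focal stages, so their per-SD effects are scaled within each
    # stage group; stage-independent covariates are scaled over all stems.
    # Scaling moments come from interior stems (edge stems have truncated
    # neighborhoods and are never analysed as focals), so the per-SD truth
    # is on the same scale a downstream per-stage analysis standardizes to.
    # A stage where a stratum is structurally undefined contributes 0.
    stage_scoped = {c for c in cov.columns if c[:2] in ("Ea", "Sa", "La")}
    b = geom.edge_buffer
    interior = (
        (census["x"] >= b) & (census["x"] <= geom.width - b)
        & (census["y"] >= b) & (census["y"] <= geom.height - b)
    ).to_numpy()
    if not interior.any():
        interior = np.ones(n, dtype=bool)

    def _z(v: np.ndarray, calib: np.ndarray) -> np.ndarray:
        ref = v[calib]
        sd = ref.std(ddof=1) if len(ref) > 1 else 0.0
        return (v - ref.mean()) / sd if sd > 0 else np.zeros_like(v)

    truth_p = config.truth
    stage_arr = census["stage"].to_numpy()
    if truth_p.stage_alpha is not None:
        eta = np.array([truth_p.stage_alpha[s] for s in stage_arr])
    else:
        eta = np.full(n, truth_p.alpha)
    for var, beta in truth_p.betas.items():
        v = cov[var].to_numpy(dtype=float)
        if var in stage_scoped:
            z = np.empty(n)
            for s in np.unique(stage_arr):
                m = stage_arr == s
                z[m] = _z(v[m], interior[m])
        else:
            z = _z(v, interior)
            if not z.any():
                raise ValueError(f"degenerate generating covariate {var}")
        eta += beta * z

    sp_codes, sp_unique = pd.factorize(census["species"])
    u_species = rng.normal(0.0, truth_p.sigma_species, size=len(sp_unique))
    n_grids = geom.n_grid_x * geom.n_grid_y
    u_grid = rng.normal(0.0, truth_p.sigma_grid, size=n_grids)
    eta = eta + u_species[sp_codes] + u_grid[census["grid_id"].to_numpy()]

    p_dead = 1.0 / (1.0 + np.exp(-eta))
    census["dead"] = (rng.uniform(size=n) < p_dead).astype(np.int8)

    truth = SyntheticTruth(
        alpha=truth_p.alpha,
        stage_alpha=dict(truth_p.stage_alpha) if truth_p.stage_alpha else None,
        betas=dict(truth_p.betas),
        sigma_species=truth_p.sigma_species,
        sigma_grid=truth_p.sigma_grid,
        radius=truth_p.radius,
        u_species=dict(zip(sp_unique, u_species)),
        u_grid=u_grid,
        linpred=eta,
        p_dead=p_dead,
    )
    return census, env, truth


def write_bundle(path_prefix, census: pd.DataFrame, env: pd.DataFrame, truth: SyntheticTruth):
    """Write census CSV (reader dialect), environment CSV and truth JSON."""
    out = census.copy()
    out["status2"] = np.where(out["dead"] == 1, "D", "A")
    cols = ["tag", "species", "x", "y", "dbh", "status2", "life_form"]
    out[cols].to_csv(f"{path_prefix}_census.csv", index=False)
    env.to_csv(f"{path_prefix}_env.csv", index=False)
    with open(f"{path_prefix}_truth.json", "w") as fh:
        fh.write(truth.to_json())
    lf = (
        census[["species", "life_form"]].drop_duplicates().sort_values("species")
    )
    lf.to_csv(f"{path_prefix}_life_forms.csv", index=False)


def sample_measured_surfaces(
    config: SyntheticConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, np.ndarray]]:
    """Altimetry at 20 m grid corners and random soil point samples drawn
    from freshly generated smooth surfaces (for exercising the kriging
    path of the terrain module)."""
    config = config or SyntheticConfig()
    rng = np.random.default_rng((config.seed if seed is None else seed) + 7)
    geom = config.geometry
    shape = (geom.n_quadrat_y + 1, geom.n_quadrat_x + 1)
    ls = config.env_length_scale / geom.quadrat_cell
    fields = {
        name: _smooth_field(rng, shape, ls, mean, sd)
        for name, (mean, sd) in ENV_FIELD_DEFAULTS.items()
    }
    cell = geom.quadrat_cell
    ys = np.arange(shape[0]) * cell
    xs = np.arange(shape[1]) * cell

    step = int(round(geom.grid_cell / cell))
    gy, gx = np.meshgrid(ys[::step], xs[::step], indexing="ij")
    altimetry = pd.DataFrame(
        {
            "x": gx.ravel(),
            "y": gy.ravel(),
            "elevation": fields["elevation"][::step, ::step].ravel(),
        }
    )

    pts = rng.uniform([0, 0], [geom.width, geom.height], size=(config.n_soil_samples, 2))
    soil = pd.DataFrame({"x": pts[:, 0], "y": pts[:, 1]})
    for var in ("tn", "tp", "ph", "smc"):
        interp = RegularGridInterpolator((ys, xs), fields[var])
        soil[var] = interp(pts[:, [1, 0]])
    return altimetry, soil, fields


def score_recovery(
    truth: SyntheticTruth, results: pd.DataFrame
) -> pd.DataFrame:
    """Per-variable recovery report: sign match, absolute error and whether
    the 1.96-SE interval covers the generating value.

    Covariates re-standardized by the analysis carry a slightly different
    per-SD scale than the generator; signs and significance compare
    exactly, absolute errors are indicative.
    """
    rows = []
    for var in results.index:
        true_beta = truth.betas.get(var, 0.0)
        est = results.loc[var, "beta_avg"]
        se = results.loc[var, "se_uncond"]
        rows.append(
            {
                "var": var,
                "true_beta": true_beta,
                "beta_avg": est,
                "sign_match": bool(np.sign(est) == np.sign(true_beta))
                if true_beta != 0 and np.isfinite(est)
                else np.nan,
                "abs_error": abs(est - true_beta) if np.isfinite(est) else np.nan,
                "ci_covers": bool(abs(est - true_beta) <= 1.96 * se)
                if np.isfinite(est) and np.isfinite(se)
                else np.nan,
                "significant": bool(results.loc[var, "significant"]),
                "importance": float(results.loc[var, "importance"]),
            }
        )
    return pd.DataFrame(rows).set_index("var")
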