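"""Exhaustive AIC model averaging over fixed-effect subsets.

Every subset of the candidate covariates (2^n models, including the
null model) is fitted as a binomial mixed model with the same crossed
random intercepts.  Each model i gets an Akaike weight

    w_i = exp(-Delta_i / 2) / sum_k exp(-Delta_k / 2),
    Delta_i = AIC_i - min AIC,

a variable's importance is the summed weight of the models containing
it, and coefficients are averaged over the "optimal model group"
(Delta AIC <= 2, weights renormalized) with an unconditional standard
error that carries both within-model and between-model uncertainty:

    beta_bar = sum_i w'_i beta_i
    SE_u     = sum_i w'_i sqrt(var_i + (beta_i - beta_bar)^2)

By default averaging is *natural* (conditional): only models containing
the variable contribute, with their weights renormalized.  Full-model
averaging (absent coefficient treated as zero) and the squared
(non-revised) SE combination are available behind flags.

The optimal neighborhood radius is chosen beforehand: for each
candidate radius a model with the pooled conspecific and heterospecific
indices as the only fixed covariates is fitted, and the radius with the
lowest AIC wins (ties break to the smallest radius).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass


import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .glmm import GlmmFit, fit_glmm, standardize_frame

log = logging.getLogger(__name__)

MAX_CANDIDATE_VARS = 16
DEFAULT_RADII = tuple(range(5, 45, 5))


# ---------------------------------------------------------------------------
# arithmetic building blocks
# ---------------------------------------------------------------------------

def enumerate_models(candidate_vars, guard: int = MAX_CANDIDATE_VARS) -> list[tuple]:
    """All subsets of the candidate variables in binary-counting order.

    Bit j of the subset mask selects candidate j, so subsets appear as
    (), (v0,), (v1,), (v0, v1), ... deterministically.
    """
    cand = list(candidate_vars)
    n = len(cand)
    if n > guard:
        raise ValueError(
            f"{n} candidate variables would require 2^{n} model fits; "
            f"raise `guard` explicitly if this is intended"
        )
    out = []
    for mask in range(2**n):
        out.append(tuple(cand[j] for j in range(n) if mask >> j & 1))
    return out


def aic_weights(aics) -> np.ndarray:
    """Akaike weights exp(-Delta/2) normalized to sum 1."""
    a = np.asarray(aics, dtype=float)
    if not np.isfinite(a).all():
        raise ValueError("non-finite AIC")
    d = a - a.min()
    w = np.exp(-d / 2.0)
    return w / w.sum()


def variable_importance(model_vars: list[tuple], weights) -> dict[str, float]:
    """Per-variable summed Akaike weight over the models containing it."""
    w = np.asarray(weights, dtype=float)
    all_vars: list[str] = []
    for mv in model_vars:
        for v in mv:
            if v not in all_vars:
                all_vars.append(v)
    return {
        v: float(w[[v in mv for mv in model_vars]].sum()) for v in all_vars
    }


def select_group(aics, delta: float = 2.0) -> np.ndarray:
    """Boolean mask of the optimal model group: AIC within ``delta`` of the
    best model.  Always contains at least the best model."""
    a = np.asarray(aics, dtype=float)
    return a - a.min() <= delta


def averaged_estimate(
    betas,
    ses,
    weights,
    mode: str = "natural",
    se_form: str = "revised",
) -> tuple[float, float]:
    """Model-averaged coefficient and unconditional SE for one variable.

    ``betas``/``ses`` hold NaN for group models not containing the
    variable.  ``mode='natural'`` renormalizes the weights over the models
    that contain it; ``mode='full'`` treats the absent coefficient as 0
    with 0 variance.  ``se_form='revised'`` uses the square-root
    combination shown in the module docstring; ``'squared'`` uses
    sqrt(sum w (var + dev^2)).
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    w = np.asarray(weights, dtype=float)
    has = ~np.isnan(b)
    if not has.any():
        return np.nan, np.nan
    if mode == "natural":
        w = w[has] / w[has].sum()
        b, s = b[has], s[has]
    elif mode == "full":
        w = w / w.sum()
        b = np.where(has, b, 0.0)
        s = np.where(has, s, 0.0)
    else:
        raise ValueError(f"unknown averaging mode {mode!r}")
    beta_avg = float(w @ b)
    dev2 = (b - beta_avg) ** 2
    if se_form == "revised":
        se = float(w @ np.sqrt(s**2 + dev2))
    elif se_form == "squared":
        se = float(np.sqrt(w @ (s**2 + dev2)))
    else:
        raise ValueError(f"unknown se_form {se_form!r}")
    return beta_avg, se


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class AICModelAverager(BaseEstimator):
    """Exhaustive-subset AIC averaging of binomial mixed models.

    Fits all 2^n subsets of the columns of ``X`` (plus the null model)
    with crossed species/grid random intercepts, then reports per-variable
    importance and model-averaged effects over the Delta AIC <= 2 group.

    Parameters
    ----------
    delta : float
        Half-width of the optimal model group (AIC units).
    mode : {'natural', 'full'}
        Conditional vs zero-filled coefficient averaging.
    se_form : {'revised', 'squared'}
        Unconditional-SE combination rule.
    standardize_X : bool
        Z-score the covariates before fitting (the analysis convention;
        disable only if ``X`` is already standardized).
    guard : int
        Refuse candidate sets larger than this (2^n fits).

    Attributes (after fit)
    ----------------------
    results_ : DataFrame (var, importance, beta_avg, se_uncond, significant)
    models_, aics_, weights_, group_ : the fitted model set
    n_dropped_ : non-converged fits removed before weighting
    """

    def __init__(
        self,
        delta: float = 2.0,
        mode: str = "natural",
        se_form: str = "revised",
        standardize_X: bool = True,
        guard: int = MAX_CANDIDATE_VARS,
        max_outer_fev: int = 200,
    ):
        self.delta = delta
        self.mode = mode
        self.se_form = se_form
        self.standardize_X = standardize_X
        self.guard = guard
        self.max_outer_fev = max_outer_fev

    def fit(self, X: pd.DataFrame, y, species=None, grid=None):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
            X.columns = [f"x{i}" for i in X.columns]
        if self.standardize_X:
            X, self.transform_ = standardize_frame(X)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        cand = list(X.columns)
        specs = enumerate_models(cand, guard=self.guard)

        # the full model's variance estimates warm-start every subset fit
        full = fit_glmm(
            y, X, species=species, grid=grid, max_outer_fev=self.max_outer_fev
        )
        theta0 = (
            max(full.sigma_species, 0.05),
            max(full.sigma_grid, 0.05),
        )

        fits: list[GlmmFit] = []
        kept_specs: list[tuple] = []
        n_dropped = 0
        for spec in specs:
            if spec == tuple(cand):
                fit = full
            else:
                fit = fit_glmm(
                    y,
                    X[list(spec)] if spec else None,
                    species=species,
                    grid=grid,
                    theta0=theta0,
                    max_outer_fev=self.max_outer_fev,
                )
            if not fit.converged:
                n_dropped += 1
                continue
            fits.append(fit)
            kept_specs.append(spec)
        if n_dropped:
            log.warning("dropped %d non-converged model(s) of %d", n_dropped, len(specs))
        if not fits:
            raise RuntimeError("no model converged")

        self.models_ = fits
        self.model_vars_ = kept_specs
        self.n_dropped_ = n_dropped
        self.aics_ = np.array([f.aic for f in fits])
        self.weights_ = aic_weights(self.aics_)
        self.importance_ = variable_importance(
            [tuple(cand)] + kept_specs, np.concatenate([[0.0], self.weights_])
        )  # seed ordering with the full candidate list, zero-weighted
        self.group_ = select_group(self.aics_, delta=self.delta)

        gw = self.weights_[self.group_]
        gw = gw / gw.sum()
        rows = []
        for v in cand:
            betas, ses = [], []
            for keep, fit in zip(self.group_, fits):
                if not keep:
                    continue
                betas.append(fit.beta.get(v, np.nan))
                ses.append(fit.bse.get(v, np.nan))
            beta_avg, se = averaged_estimate(
                betas, ses, gw, mode=self.mode, se_form=self.se_form
            )
            sig = bool(
                np.isfinite(beta_avg)
                and np.isfinite(se)
                and abs(beta_avg) > 1.96 * se
            )
            rows.append(
                {
                    "var": v,
                    "importance": self.importance_.get(v, 0.0),
                    "beta_avg": beta_avg,
                    "se_uncond": se,
                    "significant": sig,
                }
            )
        self.results_ = pd.DataFrame(rows).set_index("var")
        return self


def average_models(
    X: pd.DataFrame, y, species=None, grid=None, **kwargs
) -> pd.DataFrame:
    """Functional wrapper around :class:`AICModelAverager`; returns results_."""
    est = AICModelAverager(**kwargs)
    est.fit(X, y, species=species, grid=grid)
    return est.results_


# ---------------------------------------------------------------------------
# radius selection
# ---------------------------------------------------------------------------

@dataclass
class RadiusSelection:
    radius: float
    aic_curve: pd.DataFrame  # columns: radius, aic, converged


def select_radius(
    ni_by_radius: pd.DataFrame,
    y,
    species,
    grid,
    radii=DEFAULT_RADII,
    max_outer_fev: int = 200,
) -> RadiusSelection:
    """Pick the neighborhood radius whose pooled CON + HET model has the
    lowest AIC.

    ``ni_by_radius`` is the multi-radius frame from
    :func:`treemort.neighborhood.stratified_indices` (long over a
    'radius_key' level) restricted to the focal sample, with at least the
    CON and HET columns.  Ties break to the smallest radius.
    """
    rows = []
    best = None
    theta0 = None
    for r in radii:
        sub = ni_by_radius.xs(r, level="radius_key")
        X = pd.DataFrame({"CON": sub["CON"], "HET": sub["HET"]})
        Xz, _ = standardize_frame(X)
        fit = fit_glmm(
            y, Xz, species=species, grid=grid, theta0=theta0, max_outer_fev=max_outer_fev
        )
        theta0 = (max(fit.sigma_species, 0.05), max(fit.sigma_grid, 0.05))
        rows.append({"radius": r, "aic": fit.aic, "converged": fit.converged})
        if fit.converged and (best is None or fit.aic < best[1] - 1e-12):
            best = (r, fit.aic)
    curve = pd.DataFrame(rows)
    if best is None:
        raise RuntimeError("no radius model converged")
    ties = curve[np.isclose(curve["aic"], best[1]) & curve["converged"]]
    if len(ties) > 1:
        log.info("AIC tie across radii %s; keeping the smallest", list(ties["radius"]))
    return RadiusSelection(radius=float(best[0]), aic_curve=curve)
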