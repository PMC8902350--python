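"""Terrain and soil covariate surfaces.

Topography enters the mortality models at 5 m quadrat resolution.
Measured inputs are altimetry at the corners of the 20 m grids and
point-sampled soil properties (total N and P in g/kg, pH, volumetric
moisture).  Both are densified to the corners of the 5 m quadrats by
ordinary kriging; per-quadrat covariates are then derived:

* elevation — mean of the quadrat's four corners (m);
* convexity — quadrat elevation minus the mean elevation of its eight
  surrounding quadrats (m; undefined on the lattice boundary);
* slope — mean dip angle from horizontal of the four triangular planes
  obtained by omitting each corner in turn (degrees);
* aspect — circular mean of the four planes' downslope azimuths from
  north, reported through the continuity transform cos(alpha) + 1.1,
  which ranges over [0.1, 2.1].

Soil surfaces use the same corner-then-quadrat-mean convention as
elevation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.spatial.distance import cdist

from .census import PlotGeometry

log = logging.getLogger(__name__)

SOIL_VARS = ("tn", "tp", "ph", "smc")


# ---------------------------------------------------------------------------
# variograms and ordinary kriging
# ---------------------------------------------------------------------------

def _vgm_exponential(h, nugget, sill, rng):
    return nugget + sill * (1.0 - np.exp(-3.0 * h / rng))


def _vgm_gaussian(h, nugget, sill, rng):
    return nugget + sill * (1.0 - np.exp(-3.0 * (h / rng) ** 2))


def _vgm_spherical(h, nugget, sill, rng):
    hr = np.clip(h / rng, 0.0, 1.0)
    return nugget + sill * (1.5 * hr - 0.5 * hr**3)


VARIOGRAM_MODELS = {
    "exponential": _vgm_exponential,
    "gaussian": _vgm_gaussian,
    "spherical": _vgm_spherical,
}


@dataclass(frozen=True)
class Variogram:
    """Fitted isotropic variogram: gamma(h) = nugget + partial sill * f(h/range)."""

    model: str = "exponential"
    nugget: float = 0.0
    sill: float = 1.0
    range_: float = 50.0

    def __call__(self, h) -> np.ndarray:
        return VARIOGRAM_MODELS[self.model](np.asarray(h, dtype=float), self.nugget, self.sill, self.range_)


def empirical_variogram(
    xy: np.ndarray, values: np.ndarray, n_lags: int = 15, max_dist: float | None = None
) -> pd.DataFrame:
    """Binned semivariance 0.5 * mean (z_i - z_j)^2 against pair distance."""
    xy = np.asarray(xy, dtype=float)
    z = np.asarray(values, dtype=float)
    d = cdist(xy, xy)
    iu = np.triu_indices(len(z), k=1)
    d = d[iu]
    sq = 0.5 * (z[iu[0]] - z[iu[1]]) ** 2
    if max_dist is None:
        max_dist = d.max() / 2.0
    keep = d <= max_dist
    d, sq = d[keep], sq[keep]
    edges = np.linspace(0, max_dist, n_lags + 1)
    which = np.clip(np.digitize(d, edges) - 1, 0, n_lags - 1)
    cnt = np.bincount(which, minlength=n_lags)
    with np.errstate(invalid="ignore"):
        gamma = np.bincount(which, weights=sq, minlength=n_lags) / cnt
        hbar = np.bincount(which, weights=d, minlength=n_lags) / cnt
    ok = cnt > 0
    return pd.DataFrame({"lag": hbar[ok], "gamma": gamma[ok], "n": cnt[ok]})


def fit_variogram(
    xy: np.ndarray,
    values: np.ndarray,
    model: str = "exponential",
    n_lags: int = 15,
    max_dist: float | None = None,
    allow_nugget: bool = True,
) -> Variogram:
    """Weighted-least-squares fit of a variogram model to the empirical
    variogram (weights n_k / gamma_model^2, the usual Cressie scheme)."""
    if model not in VARIOGRAM_MODELS:
        raise ValueError(f"unknown variogram model {model!r}")
    emp = empirical_variogram(xy, values, n_lags=n_lags, max_dist=max_dist)
    h, g, n = emp["lag"].to_numpy(), emp["gamma"].to_numpy(), emp["n"].to_numpy()
    var = np.var(np.asarray(values, dtype=float))
    if var == 0 or len(h) < 3:
        return Variogram(model, 0.0, max(var, 1e-12), max(h.max() if len(h) else 1.0, 1e-6))
    f = VARIOGRAM_MODELS[model]

    def resid(p):
        nugget, sill, rng = p
        gm = f(h, nugget, sill, rng)
        return np.sqrt(n) * (g - gm) / np.maximum(gm, 1e-12)

    p0 = np.array([0.1 * var if allow_nugget else 0.0, var, h.max() / 2.0])
    lb = np.array([0.0, 1e-12, 1e-6])
    ub = np.array([var * 10 if allow_nugget else 1e-12, var * 100, h.max() * 10])
    sol = least_squares(resid, np.clip(p0, lb, ub), bounds=(lb, ub), max_nfev=200)
    nugget, sill, rng = sol.x
    return Variogram(model, float(nugget), float(sill), float(rng))


def krige(
    sample_xy: np.ndarray,
    sample_values: np.ndarray,
    target_xy: np.ndarray,
    variogram: Variogram | None = None,
    model: str = "exponential",
) -> np.ndarray:
    """Ordinary-kriging prediction at target points.

    Solves the standard OK system with Lagrange multiplier for the unknown
    constant mean; with a zero nugget predictions interpolate the samples
    exactly.  Duplicate sample locations are averaged first (the kriging
    matrix would otherwise be singular).
    """
    xy = np.asarray(sample_xy, dtype=float)
    z = np.asarray(sample_values, dtype=float)
    if len(xy) < 2:
        raise ValueError("kriging needs at least 2 sample points")

    # collapse duplicate locations by averaging
    uniq, inv = np.unique(xy.round(9), axis=0, return_inverse=True)
    if len(uniq) < len(xy):
        log.warning("averaged %d duplicate sample location(s)", len(xy) - len(uniq))
        zsum = np.bincount(inv, weights=z)
        zn = np.bincount(inv)
        xy, z = uniq, zsum / zn

    if variogram is None:
        variogram = fit_variogram(xy, z, model=model)

    n = len(xy)
    gamma = variogram(cdist(xy, xy))
    np.fill_diagonal(gamma, 0.0)
    A = np.empty((n + 1, n + 1))
    A[:n, :n] = gamma
    A[n, :n] = 1.0
    A[:n, n] = 1.0
    A[n, n] = 0.0

    targets = np.asarray(target_xy, dtype=float)
    B = np.empty((n + 1, len(targets)))
    B[:n] = variogram(cdist(xy, targets))
    B[n] = 1.0
    # tiny ridge on the diagonal for numerical safety with smooth models
    A[:n, :n] += np.eye(n) * 1e-10 * max(variogram.sill, 1.0)
    lam = np.linalg.solve(A, B)
    return lam[:n].T @ z


def krige_to_corners(
    samples: pd.DataFrame,
    value_col: str,
    geometry: PlotGeometry,
    variogram: Variogram | None = None,
    model: str = "exponential",
) -> np.ndarray:
    """Krige point samples to the 5 m quadrat-corner lattice.

    Returns an array of shape (n_quadrat_y + 1, n_quadrat_x + 1) indexed
    [row=j (y), col=i (x)] with corner (i, j) at (i*cell, j*cell).
    """
    cell = geometry.quadrat_cell
    xs = np.arange(geometry.n_quadrat_x + 1) * cell
    ys = np.arange(geometry.n_quadrat_y + 1) * cell
    gx, gy = np.meshgrid(xs, ys)
    targets = np.column_stack([gx.ravel(), gy.ravel()])
    pred = krige(
        samples[["x", "y"]].to_numpy(float),
        samples[value_col].to_numpy(float),
        targets,
        variogram=variogram,
        model=model,
    )
    return pred.reshape(len(ys), len(xs))


# ---------------------------------------------------------------------------
# per-quadrat derivations
# ---------------------------------------------------------------------------

def quadrat_mean(corners: np.ndarray) -> np.ndarray:
    """Per-quadrat mean of the four corner values.

    ``corners`` has shape (ny+1, nx+1); the result has shape (ny, nx).
    """
    c = np.asarray(corners, dtype=float)
    if not np.isfinite(c).all():
        raise ValueError("missing corner value")
    return (c[:-1, :-1] + c[:-1, 1:] + c[1:, :-1] + c[1:, 1:]) / 4.0


def convexity(quadrat_elev: np.ndarray) -> np.ndarray:
    """Center elevation minus the mean of the 8 surrounding quadrats.

    Boundary quadrats lack a full neighborhood and are NaN; after the 25 m
    edge exclusion no focal tree sits in such a quadrat.
    """
    e = np.asarray(quadrat_elev, dtype=float)
    out = np.full_like(e, np.nan)
    nb = (
        e[:-2, :-2] + e[:-2, 1:-1] + e[:-2, 2:]
        + e[1:-1, :-2] + e[1:-1, 2:]
        + e[2:, :-2] + e[2:, 1:-1] + e[2:, 2:]
    ) / 8.0
    out[1:-1, 1:-1] = e[1:-1, 1:-1] - nb
    return out


def slope_aspect(corners: np.ndarray, cell: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-quadrat slope (degrees) and transformed aspect cos(alpha) + 1.1.

    Each quadrat is split into the four triangles obtained by joining three
    of its corners.  A triangle through three points defines a plane
    z = a x + b y + c; its dip angle is arctan(hypot(a, b)) and its
    downslope azimuth is atan2(-a, -b) measured clockwise from north
    (+y).  Slope is the arithmetic mean of the four dip angles; aspect is
    the circular mean of the four azimuths (unit-vector resultant), which
    is well defined across the 0/360 wrap.  A horizontal quadrat has no
    azimuth; its transformed aspect is set to the neutral midpoint 1.1.
    """
    c = np.asarray(corners, dtype=float)
    z00 = c[:-1, :-1]  # (x0, y0)
    z10 = c[:-1, 1:]   # (x1, y0)
    z01 = c[1:, :-1]   # (x0, y1)
    z11 = c[1:, 1:]    # (x1, y1)

    # plane gradients (a, b) for the triangle omitting each corner in turn
    grads = [
        ((z11 - z01) / cell, (z01 - z00) / cell),  # omit (x1, y0)
        ((z10 - z00) / cell, (z11 - z10) / cell),  # omit (x0, y1)
        ((z10 - z00) / cell, (z01 - z00) / cell),  # omit (x1, y1)
        ((z11 - z01) / cell, (z11 - z10) / cell),  # omit (x0, y0)
    ]
    dips = []
    sin_sum = np.zeros_like(z00)
    cos_sum = np.zeros_like(z00)
    nonflat = np.zeros_like(z00)
    for a, b in grads:
        mag = np.hypot(a, b)
        dips.append(np.degrees(np.arctan(mag)))
        flat = mag == 0
        with np.errstate(invalid="ignore", divide="ignore"):
            ux = np.where(flat, 0.0, -a / np.where(flat, 1.0, mag))
            uy = np.where(flat, 0.0, -b / np.where(flat, 1.0, mag))
        sin_sum += ux  # azimuth = atan2(dx, dy) from north: sin = dx, cos = dy
        cos_sum += uy
        nonflat += ~flat
    slope = np.mean(dips, axis=0)
    resultant = np.hypot(sin_sum, cos_sum)
    aspect = np.arctan2(sin_sum, cos_sum)  # radians clockwise from north
    aspect_t = np.where((nonflat == 0) | (resultant < 1e-12), 1.1, np.cos(aspect) + 1.1)
    return slope, aspect_t


def environment_table(
    corner_elevation: np.ndarray,
    geometry: PlotGeometry,
    soil_corners: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Assemble the per-quadrat covariate table keyed by quadrat_id.

    ``corner_elevation`` (and each soil corner field) is a 5 m corner
    lattice as produced by :func:`krige_to_corners`.
    """
    elev_q = quadrat_mean(corner_elevation)
    conv_q = convexity(elev_q)
    slope_q, aspect_q = slope_aspect(corner_elevation, geometry.quadrat_cell)

    ny, nx = elev_q.shape
    qy, qx = np.mgrid[0:ny, 0:nx]
    out = pd.DataFrame(
        {
            "quadrat_id": (qy * nx + qx).ravel(),
            "elev": elev_q.ravel(),
            "conv": conv_q.ravel(),
            "slop": slope_q.ravel(),
            "aspe": aspect_q.ravel(),
        }
    )
    if soil_corners:
        for name, field in soil_corners.items():
            out[name] = quadrat_mean(field).ravel()
    return out.set_index("quadrat_id", drop=False)


def derive_environment(
    altimetry: pd.DataFrame,
    soil_samples: pd.DataFrame | None,
    geometry: PlotGeometry,
    model: str = "exponential",
) -> pd.DataFrame:
    """Full measured-inputs path: krige 20 m-corner altimetry and soil point
    samples to the 5 m corner lattice, then derive the quadrat table."""
    corner_elev = krige_to_corners(altimetry, "elevation", geometry, model=model)
    soil = {}
    if soil_samples is not None:
        for var in SOIL_VARS:
            if var in soil_samples.columns:
                soil[var] = krige_to_corners(soil_samples, var, geometry, model=model)
    return environment_table(corner_elev, geometry, soil or None)
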