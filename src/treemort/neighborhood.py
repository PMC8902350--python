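"""Distance-weighted neighborhood crowding indices.

For a focal tree *i* the neighborhood index over the stems *j* within a
radius *r* is

    NI_i = sum_j  BA_j / d_ij,        BA_j = (DBH_j / 2)^2 * pi

with basal area in cm^2 and distance in m.  The index is computed pooled
(ALL), split by conspecific vs heterospecific neighbors (CON / HET), and
further partitioned by the neighbor's life stage relative to the focal
tree (Ea / Sa / La prefixes for earlier / same / later), giving the nine
strata CON, HET, EaCON, SaCON, LaCON, EaHET, SaHET, LaHET, ALL.  The
stratified values partition exactly: Ea+Sa+La = CON (resp. HET) and
CON + HET = ALL.

Neighbor pools are always the census-1 snapshot: every stem alive at the
first census contributes, regardless of species, focal-set membership or
its own later fate.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .stages import EARLIER, LATER, SAME, STAGE_ORDER

log = logging.getLogger(__name__)

STRATA: tuple[str, ...] = (
    "CON",
    "HET",
    "EaCON",
    "SaCON",
    "LaCON",
    "EaHET",
    "SaHET",
    "LaHET",
    "ALL",
)

_REL_PREFIX = {EARLIER: "Ea", SAME: "Sa", LATER: "La"}


def basal_area(dbh) -> np.ndarray | float:
    """Basal area in cm^2 from DBH in cm: (DBH/2)^2 * pi."""
    arr = np.asarray(dbh, dtype=float)
    if (arr < 1).any():
        raise ValueError("dbh below the 1 cm census standard")
    out = (arr / 2.0) ** 2 * np.pi
    return out if out.ndim else float(out)


def _neighbor_pairs(
    focal_xy: np.ndarray, tree: cKDTree, radius: float
) -> tuple[np.ndarray, np.ndarray]:
    """(focal position index, neighbor tree index) for all pairs within
    ``radius`` (closed ball)."""
    lists = tree.query_ball_point(focal_xy, r=radius)
    counts = np.fromiter((len(l) for l in lists), dtype=np.int64, count=len(lists))
    fi = np.repeat(np.arange(len(lists)), counts)
    nj = np.concatenate([np.asarray(l, dtype=np.int64) for l in lists]) if counts.sum() else np.empty(0, dtype=np.int64)
    return fi, nj


def stratified_indices(
    trees: pd.DataFrame,
    focal: pd.DataFrame | None = None,
    radius: float = 20.0,
    radii: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Neighborhood indices for each focal tree, all strata, one or more radii.

    Parameters
    ----------
    trees : DataFrame
        Full census-1 snapshot (neighbor pool); needs columns x, y, dbh,
        species, stage and a 'tag' id.
    focal : DataFrame, optional
        Subset of ``trees`` to evaluate (defaults to all).  Rows are matched
        to the neighbor pool positionally via the index of ``trees``, so the
        focal stem itself is never counted as its own neighbor.
    radius : float
        Radius in m (ignored when ``radii`` is given).
    radii : sequence of float, optional
        Evaluate several radii in one spatial pass.

    Returns
    -------
    DataFrame indexed like ``focal`` with one column per stratum for a
    single radius, or a long frame (focal_tag, stratum, radius, value)
    when ``radii`` is given... The wide single-radius form is the working
    format; :func:`to_long` converts to the long CSV dialect.

    Coincident stems (distance exactly 0) would make the 1/d kernel
    singular; such neighbor pairs are excluded and counted in a warning.
    """
    if focal is None:
        focal = trees
    radii_arr = np.sort(np.asarray(radii if radii is not None else [radius], dtype=float))
    rmax = float(radii_arr[-1])

    pool_xy = np.column_stack([trees["x"].to_numpy(float), trees["y"].to_numpy(float)])
    focal_xy = np.column_stack([focal["x"].to_numpy(float), focal["y"].to_numpy(float)])
    kdt = cKDTree(pool_xy)

    # positional index of each focal row inside the pool (to drop self-pairs)
    pool_pos = pd.Series(np.arange(len(trees)), index=trees.index)
    focal_pos = pool_pos.reindex(focal.index).to_numpy()

    ba = basal_area(trees["dbh"].to_numpy(float))
    p_species = trees["species"].to_numpy(object)
    f_species = focal["species"].to_numpy(object)
    f_ord = np.array([STAGE_ORDER[s] for s in focal["stage"]], dtype=np.int64)
    p_ord = np.array([STAGE_ORDER[s] for s in trees["stage"]], dtype=np.int64)

    nf, nr = len(focal), len(radii_arr)
    fine = np.zeros((nf, nr, 6))
    n_coincident = 0
    # block size targets ~2e6 pairs in flight to bound memory on dense plots
    area = max(np.ptp(pool_xy[:, 0]) * np.ptp(pool_xy[:, 1]), 1.0)
    mean_neighbors = max(np.pi * rmax**2 * len(trees) / area, 1.0)
    block = int(np.clip(2e6 / mean_neighbors, 256, nf or 1))
    for lo in range(0, nf, block):
        hi = min(lo + block, nf)
        fi, nj = _neighbor_pairs(focal_xy[lo:hi], kdt, rmax)
        self_pair = ~np.isnan(focal_pos[lo:hi][fi]) & (nj == focal_pos[lo:hi][fi])
        dist = np.hypot(
            focal_xy[lo + fi, 0] - pool_xy[nj, 0], focal_xy[lo + fi, 1] - pool_xy[nj, 1]
        )
        coincident = (dist == 0) & ~self_pair
        n_coincident += int(coincident.sum())
        keep = ~self_pair & ~coincident
        fi, nj, dist = fi[keep], nj[keep], dist[keep]

        w = ba[nj] / dist
        con = f_species[lo + fi] == p_species[nj]
        rel = np.sign(p_ord[nj] - f_ord[lo + fi])  # -1 earlier, 0 same, +1 later
        # stratum slot: (conspecific? 0 : 1) * 3 + (rel + 1)
        slot = np.where(con, 0, 3) + (rel + 1)
        rband = np.searchsorted(radii_arr, dist, side="left")  # first radius >= dist
        nb = hi - lo
        flat = np.bincount(
            (fi * nr + rband) * 6 + slot, weights=w, minlength=nb * nr * 6
        )
        fine[lo:hi] = flat.reshape(nb, nr, 6)

    if n_coincident:
        log.warning(
            "excluded %d coincident-coordinate neighbor pair(s) (singular 1/d kernel)",
            n_coincident,
        )
    fine = np.cumsum(fine, axis=1)  # closed ball: d <= r

    frames = []
    for k, r in enumerate(radii_arr):
        part = fine[:, k, :]
        wide = pd.DataFrame(
            {
                "EaCON": part[:, 0],
                "SaCON": part[:, 1],
                "LaCON": part[:, 2],
                "EaHET": part[:, 3],
                "SaHET": part[:, 4],
                "LaHET": part[:, 5],
            },
            index=focal.index,
        )
        wide["CON"] = wide[["EaCON", "SaCON", "LaCON"]].sum(axis=1)
        wide["HET"] = wide[["EaHET", "SaHET", "LaHET"]].sum(axis=1)
        wide["ALL"] = wide["CON"] + wide["HET"]
        wide["radius"] = r
        frames.append(wide[list(STRATA) + ["radius"]])
    if radii is None:
        return frames[0].drop(columns="radius")
    return pd.concat(frames, keys=radii_arr, names=["radius_key"])


def neighborhood_index(
    trees: pd.DataFrame,
    focal_index,
    radius: float,
    stratum: str = "ALL",
) -> float:
    """NI of a single focal tree for one stratum (thin convenience wrapper)."""
    if stratum not in STRATA:
        raise ValueError(f"unknown stratum {stratum!r}")
    res = stratified_indices(trees, trees.loc[[focal_index]], radius=radius)
    return float(res.iloc[0][stratum])


def to_long(wide: pd.DataFrame, trees: pd.DataFrame, radius: float) -> pd.DataFrame:
    """Convert a wide stratum table to the long output dialect
    (focal_tag, stratum, radius, value)."""
    out = wide.copy()
    out["focal_tag"] = trees.loc[wide.index, "tag"].to_numpy()
    long = out.melt(
        id_vars="focal_tag", value_vars=list(STRATA), var_name="stratum", value_name="value"
    )
    long["radius"] = radius
    return long[["focal_tag", "stratum", "radius", "value"]]
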