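"""Census table I/O, grid assignment, and focal-tree filters.

The canonical in-memory container is a pandas DataFrame with one row per
stem and columns::

    tag        unique stem id
    species    species code
    x, y       map coordinates in m within the plot
    dbh        diameter at breast height in cm at the first census
    life_form  'shrub' | 'subtree' | 'canopy'
    dead       1 if the stem was dead at the second census, else 0
    stage      absolute life stage (added from life form + DBH)
    grid_id    flattened 20 m cell index
    quadrat_id flattened 5 m cell index

Analyses model the binary *dead* outcome over a 5-year census interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stages import STAGES, classify_stages

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("tag", "species", "x", "y", "dbh", "status2", "life_form")

#: ForestGEO-style status vocabulary collapsed to the binary dead flag.
_STATUS_DEAD = {"d", "dead", "1", "1.0", "true"}
_STATUS_ALIVE = {"a", "alive", "0", "0.0", "false"}


@dataclass(frozen=True)
class PlotGeometry:
    """Rectangular plot partitioned into 20 m grids and 5 m quadrats."""

    width: float = 500.0
    height: float = 400.0
    grid_cell: float = 20.0
    quadrat_cell: float = 5.0
    edge_buffer: float = 25.0

    def __post_init__(self) -> None:
        for dim in (self.width, self.height):
            if abs(dim / self.grid_cell - round(dim / self.grid_cell)) > 1e-9:
                raise ValueError("plot dimensions must be divisible by grid_cell")
        ratio = self.grid_cell / self.quadrat_cell
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("grid_cell must be divisible by quadrat_cell")
        if self.edge_buffer < 0:
            raise ValueError("edge_buffer must be >= 0")

    @property
    def n_grid_x(self) -> int:
        return int(round(self.width / self.grid_cell))

    @property
    def n_grid_y(self) -> int:
        return int(round(self.height / self.grid_cell))

    @property
    def n_quadrat_x(self) -> int:
        return int(round(self.width / self.quadrat_cell))

    @property
    def n_quadrat_y(self) -> int:
        return int(round(self.height / self.quadrat_cell))


def assign_cell(
    x, y, cell: float, width: float, height: float
) -> tuple[np.ndarray, np.ndarray]:
    """Zero-based cell indices under half-open intervals [k*cell, (k+1)*cell).

    Coordinates exactly on the far plot boundary are clamped into the last
    cell so that x == width never produces an off-plot index.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if ((x < 0) | (x > width) | (y < 0) | (y > height)).any():
        raise ValueError("coordinate outside plot bounds")
    ix = np.minimum(np.floor(x / cell).astype(int), int(round(width / cell)) - 1)
    iy = np.minimum(np.floor(y / cell).astype(int), int(round(height / cell)) - 1)
    return ix, iy


def _flatten(ix: np.ndarray, iy: np.ndarray, nx: int) -> np.ndarray:
    return iy * nx + ix


def add_cell_ids(df: pd.DataFrame, geometry: PlotGeometry) -> pd.DataFrame:
    """Attach grid_id (20 m) and quadrat_id (5 m) columns from x, y."""
    out = df.copy()
    gx, gy = assign_cell(out["x"], out["y"], geometry.grid_cell, geometry.width, geometry.height)
    qx, qy = assign_cell(out["x"], out["y"], geometry.quadrat_cell, geometry.width, geometry.height)
    out["grid_id"] = _flatten(gx, gy, geometry.n_grid_x)
    out["quadrat_id"] = _flatten(qx, qy, geometry.n_quadrat_x)
    return out


def _parse_status(values: pd.Series) -> np.ndarray:
    """Map a census-2 status column (A/D codes or 0/1 flags) to dead in {0,1}."""
    s = values.astype(str).str.strip().str.lower()
    dead = np.where(s.isin(_STATUS_DEAD), 1, np.where(s.isin(_STATUS_ALIVE), 0, -1))
    return dead


def validate_census(
    df: pd.DataFrame, geometry: PlotGeometry
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Validate a raw census table; return (records, rejects).

    Rejected rows carry a ``reason`` column.  Row order of accepted rows is
    preserved.  DBH below the 1 cm census floor, coordinates off the plot,
    unknown life forms and unparseable status codes are rejected, never
    silently fixed.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"census table missing column(s): {missing}")

    df = df.copy()
    reasons = pd.Series("", index=df.index, dtype=object)

    dbh = pd.to_numeric(df["dbh"], errors="coerce")
    x = pd.to_numeric(df["x"], errors="coerce")
    y = pd.to_numeric(df["y"], errors="coerce")
    dead = _parse_status(df["status2"])

    bad_dbh = dbh.isna() | (dbh < 1)
    bad_xy = (
        x.isna() | y.isna() | (x < 0) | (x > geometry.width) | (y < 0) | (y > geometry.height)
    )
    bad_form = ~df["life_form"].isin(("shrub", "subtree", "canopy"))
    bad_status = dead < 0

    reasons[bad_status] = "unparseable census-2 status"
    reasons[bad_form] = "unknown life form"
    reasons[bad_xy] = "coordinate outside plot"
    reasons[bad_dbh] = "dbh missing or below 1 cm"

    bad = reasons != ""
    rejects = df.loc[bad].copy()
    rejects["reason"] = reasons[bad]
    if bad.any():
        log.warning("rejected %d census row(s)", int(bad.sum()))

    ok = df.loc[~bad].copy()
    ok["dbh"] = dbh[~bad]
    ok["x"] = x[~bad]
    ok["y"] = y[~bad]
    ok["dead"] = dead[~bad].astype(np.int8)
    ok = ok.drop(columns=["status2"])
    ok["tag"] = ok["tag"].astype(str)
    ok["species"] = ok["species"].astype(str)
    if len(ok):
        ok["stage"] = classify_stages(ok["life_form"], ok["dbh"])
        ok = add_cell_ids(ok, geometry)
    else:
        ok["stage"] = pd.Series(dtype=object)
        ok["grid_id"] = pd.Series(dtype=int)
        ok["quadrat_id"] = pd.Series(dtype=int)
    return ok.reset_index(drop=True), rejects.reset_index(drop=True)


def read_census(
    path, geometry: PlotGeometry | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate a census CSV; returns (records, rejects)."""
    geometry = geometry or PlotGeometry()
    raw = pd.read_csv(path)
    raw.columns = [c.lower() for c in raw.columns]
    if "status" in raw.columns and "status2" not in raw.columns:
        raw = raw.rename(columns={"status": "status2"})
    return validate_census(raw, geometry)


def write_census(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def exclude_edge(records: pd.DataFrame, geometry: PlotGeometry) -> pd.DataFrame:
    """Focal subset with a complete neighborhood: distance to every plot
    edge at least ``edge_buffer`` (closed boundary — a tree exactly at the
    buffer distance is retained).  Removed trees remain valid neighbors.
    """
    b = geometry.edge_buffer
    if b >= min(geometry.width, geometry.height) / 2:
        raise ValueError("edge buffer leaves no plot interior")
    keep = (
        (records["x"] >= b)
        & (records["x"] <= geometry.width - b)
        & (records["y"] >= b)
        & (records["y"] <= geometry.height - b)
    )
    return records.loc[keep]


def select_focal_species(records: pd.DataFrame, min_per_stage: int = 50) -> list[str]:
    """Species with at least ``min_per_stage`` individuals in *every* stage.

    Smaller per-stage samples make the stage-stratified models unstable, so
    such species are excluded from the focal set (they still count as
    neighbors).
    """
    if records.empty:
        return []
    counts = records.groupby(["species", "stage"], observed=True).size().unstack(fill_value=0)
    for s in STAGES:
        if s not in counts.columns:
            counts[s] = 0
    ok = (counts[list(STAGES)] >= min_per_stage).all(axis=1)
    return sorted(counts.index[ok].astype(str))
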