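"""Ontogenetic stage classification.

Every species in the plot belongs to one of three life forms (shrub,
subtree, canopy tree), and each life form has its own DBH thresholds
splitting stems into sapling, juvenile and adult stages.  Neighbors are
then described *relative* to a focal tree as earlier, same or later
stage; sapling focals admit no earlier neighbors and adult focals no
later ones.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

SAPLING = "sapling"
JUVENILE = "juvenile"
ADULT = "adult"
STAGES: tuple[str, ...] = (SAPLING, JUVENILE, ADULT)
STAGE_ORDER: dict[str, int] = {s: i for i, s in enumerate(STAGES)}

EARLIER = "earlier"
SAME = "same"
LATER = "later"

LIFE_FORMS: tuple[str, ...] = ("shrub", "subtree", "canopy")

#: (lower juvenile bound, lower adult bound) in cm DBH per life form.
#: Intervals are lower-closed / upper-open: e.g. a shrub is a juvenile on
#: [2, 4) cm and an adult at >= 4 cm.
STAGE_THRESHOLDS: dict[str, tuple[float, float]] = {
    "shrub": (2.0, 4.0),
    "subtree": (3.0, 6.0),
    "canopy": (5.0, 10.0),
}


def classify_stage(life_form: str, dbh: float) -> str:
    """Return the absolute life stage of a stem.

    Parameters
    ----------
    life_form : {'shrub', 'subtree', 'canopy'}
    dbh : float
        Diameter at breast height in cm; the census floor is 1 cm.
    """
    if life_form not in STAGE_THRESHOLDS:
        raise ValueError(f"unknown life form: {life_form!r}")
    if dbh < 1:
        raise ValueError(f"dbh {dbh} below the 1 cm census standard")
    juv, adu = STAGE_THRESHOLDS[life_form]
    if dbh < juv:
        return SAPLING
    if dbh < adu:
        return JUVENILE
    return ADULT


def classify_stages(life_form: Sequence[str], dbh: Sequence[float]) -> np.ndarray:
    """Vectorized :func:`classify_stage` over aligned arrays."""
    life_form = np.asarray(life_form, dtype=object)
    dbh = np.asarray(dbh, dtype=float)
    unknown = ~np.isin(life_form, LIFE_FORMS)
    if unknown.any():
        bad = sorted(set(life_form[unknown]))
        raise ValueError(f"unknown life form(s): {bad}")
    if (dbh < 1).any():
        raise ValueError("dbh below the 1 cm census standard")
    juv = np.array([STAGE_THRESHOLDS[f][0] for f in life_form])
    adu = np.array([STAGE_THRESHOLDS[f][1] for f in life_form])
    out = np.where(dbh < juv, SAPLING, np.where(dbh < adu, JUVENILE, ADULT))
    return out.astype(object)


def relative_stage(focal_stage: str, neighbor_stage: str) -> str:
    """Position of a neighbor's stage relative to the focal tree's.

    Stages are ordered sapling < juvenile < adult; the comparison uses
    stage labels only, so a juvenile shrub neighbor of a canopy sapling
    counts as *later* even if its DBH is smaller.
    """
    fo = STAGE_ORDER[focal_stage]
    ne = STAGE_ORDER[neighbor_stage]
    if ne < fo:
        return EARLIER
    if ne > fo:
        return LATER
    return SAME


def admissible_relative_stages(focal_stage: str) -> tuple[str, ...]:
    """Relative stages that exist for a focal tree of the given stage."""
    if focal_stage == SAPLING:
        return (SAME, LATER)
    if focal_stage == ADULT:
        return (EARLIER, SAME)
    return (EARLIER, SAME, LATER)


def read_life_form_table(path) -> dict[str, str]:
    """Read a two-column species -> life form lookup table (CSV)."""
    df = pd.read_csv(path)
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    if not {"species", "life_form"} <= set(cols):
        raise ValueError("life-form table needs columns 'species' and 'life_form'")
    bad = set(df["life_form"]) - set(LIFE_FORMS)
    if bad:
        raise ValueError(f"unknown life form(s) in table: {sorted(bad)}")
    return dict(zip(df["species"].astype(str), df["life_form"]))
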