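"""Per-grid mortality by life stage and paired stage comparisons.

Mortality over the census interval is summarized per 20 m grid cell and
life stage, and stages are compared with the Wilcoxon signed-rank test
on within-grid differences (grids lacking either stage of a pair are
dropped pairwise).  Zero differences are removed before ranking and tied
absolute differences are mid-ranked; the null distribution is exact for
up to 25 informative pairs without rank ties, and a normal approximation
with continuity correction otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .stages import STAGES


def grid_stage_mortality(records: pd.DataFrame) -> pd.DataFrame:
    """Mortality per (grid, stage): rows only where >= 1 census-1 stem.

    ``records`` is a validated census frame with stage, grid_id and dead
    columns; typically the focal sample.
    """
    g = (
        records.groupby(["grid_id", "stage"], observed=True)
        .agg(n_alive_c1=("dead", "size"), n_dead_c2=("dead", "sum"))
        .reset_index()
    )
    g["mortality"] = g["n_dead_c2"] / g["n_alive_c1"]
    return g


@dataclass
class SignedRankResult:
    statistic: float  # W+ : sum of ranks of positive differences
    p_value: float  # two-sided; NaN when undefined (no informative pairs)
    n_pairs: int  # informative (non-zero-difference) pairs
    method: str


def wilcoxon_signed_rank(a, b, exact_max_n: int = 25) -> SignedRankResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Pairs with a missing value in either sample are dropped, then zero
    differences are discarded.  The statistic is W+, the rank sum of the
    positive differences.  With all differences zero the p-value is
    undefined and reported as NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    ok = ~(np.isnan(a) | np.isnan(b))
    d = a[ok] - b[ok]
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return SignedRankResult(np.nan, np.nan, 0, "undefined")
    has_ties = len(np.unique(np.abs(d))) < n
    if n <= exact_max_n and not has_ties:
        method = "exact"
        res = stats.wilcoxon(d, alternative="two-sided", method="exact", zero_method="wilcox")
    else:
        method = "normal-cc"
        res = stats.wilcoxon(
            d, alternative="two-sided", method="approx", correction=True, zero_method="wilcox"
        )
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    return SignedRankResult(w_plus, float(res.pvalue), n, method)


def stage_mortality_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Abundance, deaths, overall and median per-grid mortality by stage."""
    per_grid = grid_stage_mortality(records)
    rows = []
    for stage in STAGES:
        sub = records[records["stage"] == stage]
        gm = per_grid[per_grid["stage"] == stage]["mortality"]
        rows.append(
            {
                "stage": stage,
                "abundance": len(sub),
                "deaths": int(sub["dead"].sum()),
                "mortality_pct": 100.0 * sub["dead"].mean() if len(sub) else np.nan,
                "median_grid_mortality": gm.median() if len(gm) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def pairwise_stage_tests(records: pd.DataFrame) -> pd.DataFrame:
    """All three pairwise stage comparisons of per-grid mortality."""
    per_grid = grid_stage_mortality(records)
    wide = per_grid.pivot(index="grid_id", columns="stage", values="mortality")
    rows = []
    for s1, s2 in combinations(STAGES, 2):
        if s1 not in wide.columns or s2 not in wide.columns:
            continue
        res = wilcoxon_signed_rank(wide[s1], wide[s2])
        rows.append(
            {
                "stage_a": s1,
                "stage_b": s2,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "n_pairs": res.n_pairs,
                "method": res.method,
            }
        )
    return pd.DataFrame(rows)
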