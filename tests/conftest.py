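from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_census() -> pd.DataFrame:
    """A 100 x 100 m random stand with stages, cell ids and fates."""
    from treemort.census import PlotGeometry, add_cell_ids
    from treemort.stages import classify_stages

    rng = np.random.default_rng(42)
    n = 600
    df = pd.DataFrame(
        {
            "tag": [f"t{i:04d}" for i in range(n)],
            "species": rng.choice([f"sp{k}" for k in range(6)], n),
            "x": rng.uniform(0, 100, n),
            "y": rng.uniform(0, 100, n),
            "dbh": 1.0 + rng.exponential(4.0, n),
            "life_form": rng.choice(["shrub", "subtree", "canopy"], n),
            "dead": rng.integers(0, 2, n).astype(np.int8),
        }
    )
    df["stage"] = classify_stages(df["life_form"], df["dbh"])
    geom = PlotGeometry(width=100, height=100, edge_buffer=10)
    return add_cell_ids(df, geom)


@pytest.fixture(scope="session")
def small_geometry():
    from treemort.census import PlotGeometry

    return PlotGeometry(width=100, height=100, edge_buffer=10)
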