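from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree

from treemort.census import PlotGeometry
from treemort.synthetic import (
    SyntheticConfig,
    TruthParams,
    generate_plot,
    sample_measured_surfaces,
    score_recovery,
    write_bundle,
)


def _small_config(seed=0, **truth_kw):
    return SyntheticConfig(
        geometry=PlotGeometry(width=200, height=200),
        n_species=10,
        parents_per_species=10.0,
        seed=seed,
        truth=TruthParams(**truth_kw) if truth_kw else TruthParams(),
    )


class TestDeterminismAndShape:
    def test_same_seed_identical_census(self):
        c1, e1, t1 = generate_plot(_small_config(seed=5))
        c2, e2, t2 = generate_plot(_small_config(seed=5))
        pd.testing.assert_frame_equal(c1, c2)
        pd.testing.assert_frame_equal(e1, e2)
        np.testing.assert_array_equal(t1.u_grid, t2.u_grid)

    def test_different_seed_differs(self):
        c1, _, _ = generate_plot(_small_config(seed=1))
        c2, _, _ = generate_plot(_small_config(seed=2))
        assert len(c1) != len(c2) or not c1["x"].equals(c2["x"])

    def test_census_dialect_roundtrip(self, tmp_path):
        from treemort.census import read_census

        cfg = _small_config(seed=3)
        census, env, truth = generate_plot(cfg)
        write_bundle(tmp_path / "syn", census, env, truth)
        records, rejects = read_census(tmp_path / "syn_census.csv", cfg.geometry)
        assert len(records) == len(census)
        assert len(rejects) == 0
        np.testing.assert_array_equal(records["dead"].to_numpy(), census["dead"].to_numpy())


class TestGroundTruthMortality:
    def test_null_model_hits_configured_rate(self):
        # alpha = logit(0.1), no effects, no random variation: realized
        # mortality must sit within binomial sampling error of 10%
        cfg = SyntheticConfig(
            geometry=PlotGeometry(width=400, height=300),
            n_species=30,
            parents_per_species=25.0,
            seed=11,
            truth=TruthParams(
                alpha=float(np.log(0.1 / 0.9)), stage_alpha=None, betas={},
                sigma_species=0.0, sigma_grid=0.0, radius=10.0,
            ),
        )
        census, _, truth = generate_plot(cfg)
        n = len(census)
        assert n > 40_000
        rate = census["dead"].mean()
        assert abs(rate - 0.1) < 3 * np.sqrt(0.1 * 0.9 / n)
        np.testing.assert_allclose(truth.p_dead, 0.1, atol=1e-12)

    def test_mortality_monotone_in_effect_size(self):
        cfg_lo = _small_config(seed=9, betas={"LaCON": 0.3})
        cfg_hi = _small_config(seed=9, betas={"LaCON": 0.8})
        c_lo, _, t_lo = generate_plot(cfg_lo)
        c_hi, _, t_hi = generate_plot(cfg_hi)
        # same seed: identical stems, same uniform draws; trees with above-
        # average crowding can only flip toward death
        z = t_hi.linpred - t_lo.linpred
        high = z > 0
        assert (c_hi.loc[high, "dead"] >= c_lo.loc[high, "dead"]).all()
        assert c_hi.loc[high, "dead"].mean() > c_lo.loc[high, "dead"].mean()


class TestStructure:
    def test_reverse_j_dbh_distribution(self):
        cfg = SyntheticConfig(
            geometry=PlotGeometry(width=300, height=300),
            n_species=15, parents_per_species=15.0, seed=4,
        )
        census, _, _ = generate_plot(cfg)
        assert len(census) > 10_000
        dbh = census["dbh"].to_numpy()
        assert dbh.mean() == pytest.approx(1 + 1 / 0.215, abs=2 * (1 / 0.215) / np.sqrt(len(dbh)))
        counts, _ = np.histogram(dbh, bins=np.arange(1.0, 16.0))
        assert (np.diff(counts) < 0).all()
        assert (dbh < 4).mean() > 0.45  # majority of stems are small

    def test_species_patterns_aggregated_clark_evans(self):
        cfg = _small_config(seed=6)
        cfg = SyntheticConfig(
            geometry=cfg.geometry, n_species=cfg.n_species,
            parents_per_species=cfg.parents_per_species,
            dispersal_sd=8.0, seed=6,
        )
        census, _, _ = generate_plot(cfg)
        area = cfg.geometry.width * cfg.geometry.height
        below = 0
        species = census["species"].unique()
        for sp in species:
            pts = census.loc[census["species"] == sp, ["x", "y"]].to_numpy()
            if len(pts) < 50:
                continue
            d, _ = cKDTree(pts).query(pts, k=2)
            ce = 2.0 * np.sqrt(len(pts) / area) * d[:, 1].mean()
            below += ce < 1.0
        assert below == len(species)

    def test_stage_baseline_ordering_recovered(self):
        # default scenario: baseline mortality declines sapling -> adult,
        # and the per-grid medians plus signed-rank test detect it
        from treemort.mortality import pairwise_stage_tests, stage_mortality_summary

        cfg = SyntheticConfig(
            geometry=PlotGeometry(width=300, height=300),
            n_species=15, parents_per_species=15.0, seed=13,
        )
        census, _, _ = generate_plot(cfg)
        summ = stage_mortality_summary(census).set_index("stage")
        assert (
            summ.loc["sapling", "mortality_pct"]
            > summ.loc["juvenile", "mortality_pct"]
            > summ.loc["adult", "mortality_pct"]
        )
        tests = pairwise_stage_tests(census).set_index(["stage_a", "stage_b"])
        assert tests.loc[("sapling", "adult"), "p_value"] < 0.001

    def test_measured_surface_sampling(self):
        cfg = _small_config(seed=2)
        alt, soil, fields = sample_measured_surfaces(cfg)
        geom = cfg.geometry
        assert len(alt) == (geom.n_grid_x + 1) * (geom.n_grid_y + 1)
        assert len(soil) == cfg.n_soil_samples
        assert {"tn", "tp", "ph", "smc"} <= set(soil.columns)


class TestScoreRecovery:
    def test_report_fields(self):
        _, _, truth = generate_plot(_small_config(seed=1))
        results = pd.DataFrame(
            {
                "importance": [0.95, 0.2],
                "beta_avg": [0.25, -0.01],
                "se_uncond": [0.05, 0.04],
                "significant": [True, False],
            },
            index=pd.Index(["LaCON", "ELEV"], name="var"),
        )
        rep = score_recovery(truth, results)
        assert rep.loc["LaCON", "sign_match"] == True  # noqa: E712
        assert rep.loc["LaCON", "ci_covers"] == True  # noqa: E712
        assert rep.loc["ELEV", "true_beta"] == 0.0

    def test_degenerate_intensity_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(parents_per_species=0.0)
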