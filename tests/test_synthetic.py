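import numpy as np
import pandas as pd
import pytest

from plume_ed.synthetic import (
    SimulationConfig,
    simulate_colony_panel,
    simulate_dataset,
    simulate_mixed_response,
    simulate_psd,
    simulate_sites,
    simulate_water_quality,
    psd_enrichment,
)


class TestSites:
    def test_two_sites_are_exact_endpoints(self):
        s = simulate_sites(2, 0.19, 34.8)
        assert list(s["distance_km"]) == [0.19, 34.8]

    def test_three_sites_middle_is_geometric_mean(self):
        s = simulate_sites(3, 0.19, 34.8)
        expected = 10 ** ((np.log10(0.19) + np.log10(34.8)) / 2)
        assert s["distance_km"][1] == pytest.approx(expected, rel=1e-12)
        assert s["distance_km"][1] == pytest.approx(2.571, abs=5e-4)

    def test_distances_strictly_increasing_unique_ids(self):
        s = simulate_sites(17, 0.19, 34.8)
        assert np.all(np.diff(s["distance_km"]) > 0)
        assert s["site_id"].is_unique

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            simulate_sites(1, 0.19, 34.8)
        with pytest.raises(ValueError):
            simulate_sites(5, -1.0, 34.8)
        with pytest.raises(ValueError):
            simulate_sites(5, 34.8, 0.19)


class TestWaterQuality:
    def test_noise_free_zero_slope_is_constant(self):
        config = SimulationConfig(
            decay_slope_per_metric={"ntu": 0.0, "dli": 0.0, "depo": 0.0},
            intercept_per_metric={"ntu": 1.0, "dli": 2.0, "depo": -1.0},
            n_days=30,
            baseline_days=10,
        ).noise_free()
        sites = simulate_sites(4, 0.19, 34.8)
        wq = simulate_water_quality(config, sites, seed=0)
        np.testing.assert_allclose(wq["ntu"], 10.0)
        np.testing.assert_allclose(wq["dli"], 4.0)

    def test_noise_free_log10_backtransform(self):
        # log10(NTU) = 1.0 - 0.5*log10(d): NTU(1 km) = 10, NTU(10 km) = 10^0.5
        config = SimulationConfig(
            decay_slope_per_metric={"ntu": -0.5, "dli": 0.0, "depo": 0.0},
            intercept_per_metric={"ntu": 1.0, "dli": 2.0, "depo": 0.0},
            n_days=5,
            baseline_days=0,
        ).noise_free()
        sites = pd.DataFrame({"site_id": ["A", "B"], "distance_km": [1.0, 10.0]})
        wq = simulate_water_quality(config, sites, seed=0)
        np.testing.assert_allclose(wq.loc[wq.site_id == "A", "ntu"], 10.0)
        np.testing.assert_allclose(
            wq.loc[wq.site_id == "B", "ntu"], 10**0.5, rtol=1e-12
        )

    def test_baseline_has_no_distance_gradient(self):
        config = SimulationConfig(n_days=30, baseline_days=30).noise_free()
        sites = simulate_sites(5, 0.19, 34.8)
        wq = simulate_water_quality(config, sites, seed=0)
        baseline = wq[wq["day"] < 0]
        for col in ("ntu", "dli", "depo_raw"):
            assert baseline.groupby("site_id")[col].mean().nunique() == 1

    def test_natural_scales_are_valid(self, small_config, sites17):
        wq = simulate_water_quality(small_config, sites17, seed=3)
        assert (wq["ntu"] > 0).all()
        assert (wq["dli"] >= 0).all()
        assert (wq["depo_raw"] >= 0).all()

    def test_determinism_contract(self, small_config, sites17):
        a = simulate_water_quality(small_config, sites17, seed=9)
        b = simulate_water_quality(small_config, sites17, seed=9)
        c = simulate_water_quality(small_config, sites17, seed=10)
        pd.testing.assert_frame_equal(a, b)
        assert not a["ntu"].equals(c["ntu"])


class TestColonyPanel:
    def test_branching_and_corymbose_never_smother(self, sites17):
        config = SimulationConfig(
            n_days=140,
            colonies_per_site=30,
            massive_min_per_site=0,
            morphology_mix={"branching": 0.5, "corymbose": 0.5},
            smother_logit_intercept=5.0,  # extreme deposition pressure
            smother_logit_slope=0.0,
        )
        panel = simulate_colony_panel(config, sites17, seed=1)
        assert (panel["sediment_score"] == 1).all()

    def test_flat_half_probability_exceedance(self, sites17):
        # slope 0, intercept logit(0.5)=0: exceedance should be ~0.5
        config = SimulationConfig(
            n_days=280,
            colonies_per_site=40,
            massive_min_per_site=0,
            morphology_mix={"encrusting": 1.0},
            smother_logit_intercept=0.0,
            smother_logit_slope=0.0,
            dislodged_fraction=0.0,
        )
        panel = simulate_colony_panel(config, sites17, seed=2)
        n = len(panel)
        p_hat = (panel["sediment_score"] >= 3).mean()
        # three-sigma binomial band at the realised n
        assert abs(p_hat - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_zero_days_empty_panel(self, sites17):
        config = SimulationConfig(n_days=0)
        panel = simulate_colony_panel(config, sites17, seed=0)
        assert panel.empty

    def test_morphology_and_site_fixed_per_colony(self, small_config, sites17):
        panel = simulate_colony_panel(small_config, sites17, seed=5)
        per_colony = panel.groupby("colony_id")[["site_id", "morphology"]].nunique()
        assert (per_colony == 1).all().all()

    def test_mucus_scores_only_on_massive(self, small_config, sites17):
        panel = simulate_colony_panel(small_config, sites17, seed=5)
        massive = panel["morphology"] == "massive"
        assert panel.loc[massive, "mucus_score"].notna().all()
        assert panel.loc[~massive, "mucus_score"].isna().all()


class TestPSD:
    def test_closure_to_100(self, small_config, sites17):
        psd = simulate_psd(small_config, sites17, seed=4)
        sums = psd[["gravel", "sand", "silt", "clay"]].sum(axis=1)
        np.testing.assert_allclose(sums, 100.0, atol=1e-9)

    def test_no_enrichment_means_equal_expectations(self, sites17):
        config = SimulationConfig(psd_enrichment_near=1.0).noise_free()
        psd = simulate_psd(config, sites17, seed=0)
        before = psd[psd.phase == "before"].set_index("site_id")
        after = psd[psd.phase == "after_1"].set_index("site_id")
        np.testing.assert_allclose(
            before["silt"] + before["clay"], after["silt"] + after["clay"]
        )

    def test_noise_free_near_site_ratio_is_five(self):
        config = SimulationConfig(psd_enrichment_near=5.0).noise_free()
        sites = simulate_sites(2, 0.19, 34.8)
        psd = simulate_psd(config, sites, seed=0)
        near = psd[psd.site_id == "S01"].set_index("phase")
        ratio = (near.loc["after_1", "silt"] + near.loc["after_1", "clay"]) / (
            near.loc["before", "silt"] + near.loc["before", "clay"]
        )
        assert ratio == pytest.approx(5.0, rel=1e-12)

    def test_enrichment_declines_to_one_at_far_site(self):
        enr = psd_enrichment(np.array([0.19, 34.8]), 5.0, 0.19, 34.8)
        np.testing.assert_allclose(enr, [5.0, 1.0])


class TestDatasetAndTruth:
    def test_dataset_referential_integrity(self, small_config):
        ds = simulate_dataset(small_config)
        site_ids = set(ds.sites["site_id"])
        for table in (ds.water_quality, ds.colonies, ds.psd):
            assert set(table["site_id"]) <= site_ids
        assert (ds.sites["distance_km"] > 0).all()
        assert ds.truth is small_config

    def test_byte_identical_csv_under_same_seed(self, small_config, tmp_path):
        a = simulate_dataset(small_config)
        b = simulate_dataset(small_config)
        a.to_csv(tmp_path / "a")
        b.to_csv(tmp_path / "b")
        for name in ("sites", "water_quality", "colonies", "psd"):
            assert (tmp_path / "a" / f"{name}.csv").read_bytes() == (
                tmp_path / "b" / f"{name}.csv"
            ).read_bytes()


def test_variance_decomposition_recovers_components():
    """Two-way method-of-moments estimates of the site, fortnight and
    residual variances converge on the generating values at large n."""
    sd_site, sd_fort, sd_resid = 0.3, 0.2, 0.25
    d = np.logspace(np.log10(0.19), np.log10(34.8), 800)
    panel = simulate_mixed_response(
        d, 600, beta0=1.0, beta1=-0.8,
        sd_site=sd_site, sd_fortnight=sd_fort, sd_resid=sd_resid, seed=99,
    )
    S, F = 800, 600
    wide = panel.pivot_table(index="site_id", columns="fortnight", values="y")
    y = wide.to_numpy()
    x = np.log10(panel.groupby("site_id", sort=True)["distance_km"].first().to_numpy())
    # detrend site means before the variance decomposition
    site_means = y.mean(axis=1)
    coef = np.polyfit(x, site_means, 1)
    site_resid = site_means - np.polyval(coef, x)
    fort_means = y.mean(axis=0)
    interior = y - site_means[:, None] - fort_means[None, :] + y.mean()
    var_e = (interior**2).sum() / ((S - 1) * (F - 1))
    var_u = site_resid.var(ddof=2) - var_e / F
    var_v = fort_means.var(ddof=1) - var_e / S
    assert var_e == pytest.approx(sd_resid**2, rel=0.1)
    assert var_u == pytest.approx(sd_site**2, rel=0.1)
    assert var_v == pytest.approx(sd_fort**2, rel=0.1)


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(d_near_km=5.0, d_far_km=1.0)
    with pytest.raises(ValueError):
        SimulationConfig(morphology_mix={"massive": 0.5})
    with pytest.raises(ValueError):
        SimulationConfig(sd_site={"ntu": -0.1, "dli": 0.1, "depo": 0.1})
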