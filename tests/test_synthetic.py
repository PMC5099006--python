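"""Synthetic-data generator: determinism, structure, end-to-end recovery."""

import numpy as np
import pytest

from firesync import (
    SyntheticConfig,
    detect_fire_events,
    mc_envelopes,
    scar_summary,
    select_models,
    simulate_climate,
    simulate_dataset,
    simulate_fires,
    simulate_landscape,
    simulate_tree_records,
    verify_single_scar_events,
)


class TestClimate:
    def test_white_noise_when_phi_zero(self):
        cfg = SyntheticConfig(ar_phi={"PDSI": 0.0, "ENSO": 0.0,
                                      "PDO": 0.0, "AO": 0.0})
        clim = simulate_climate(cfg, seed=0)
        x = clim["AO"].values
        r1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert abs(r1) < 0.1

    def test_ar1_autocorrelation_recovered(self):
        cfg = SyntheticConfig(ar_phi={"PDSI": 0.3, "ENSO": 0.5,
                                      "PDO": 0.7, "AO": 0.3})
        clim = simulate_climate(cfg, seed=1)
        x = clim["PDO"].values
        r1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert abs(r1 - 0.7) < 0.1

    def test_pdsi_range_and_scale(self):
        clim = simulate_climate(SyntheticConfig(), seed=2)
        v = clim["PDSI"].values
        assert v.min() >= -6.0 and v.max() <= 6.0
        assert 1.5 < v.std() < 2.5

    def test_determinism(self):
        cfg = SyntheticConfig()
        a = simulate_climate(cfg, seed=3)
        b = simulate_climate(cfg, seed=3)
        for name in a:
            assert np.array_equal(a[name].values, b[name].values)

    def test_invalid_phi_rejected(self):
        with pytest.raises(ValueError, match=r"\(-1, 1\)"):
            SyntheticConfig(ar_phi={"PDSI": 1.0, "ENSO": 0.5,
                                    "PDO": 0.7, "AO": 0.3})

    def test_enso_pdo_cross_correlated(self):
        clim = simulate_climate(SyntheticConfig(enso_pdo_cross_corr=0.8),
                                seed=4)
        r = np.corrcoef(clim["ENSO"].values, clim["PDO"].values)[0, 1]
        assert r > 0.3


class TestLandscape:
    def test_attributes_in_range(self):
        lan = simulate_landscape(SyntheticConfig(), seed=0)
        assert len(lan) == 30
        assert lan["elevation_m"].between(0, 150).all()
        assert (lan["dist_habitation_m"] >= 0).all()
        assert set(lan["vegetation_type"]) <= {
            "zonal", "bog_forest", "bog_woodland", "blanket_bog"
        }


class TestFires:
    def test_homogeneous_when_no_drivers(self):
        from scipy.stats import chisquare

        cfg = SyntheticConfig(beta_dist=0.0, forcing={}, beta0=-4.5)
        clim = simulate_climate(cfg, seed=0)
        lan = simulate_landscape(cfg, seed=1)
        nonsig = 0
        for s in range(10):
            gt = simulate_fires(lan, cfg, clim, seed=s)
            counts = np.array(
                [len(gt.fire_years_by_plot[p]) for p in lan["plot_id"]]
            )
            _, p = chisquare(counts)
            nonsig += p > 0.05
        assert nonsig >= 8

    def test_distance_decay_in_fire_counts(self):
        cfg = SyntheticConfig(beta_dist=-0.004, beta0=-5.5, forcing={})
        clim = simulate_climate(cfg, seed=0)
        lan = simulate_landscape(cfg, seed=1)
        gt = simulate_fires(lan, cfg, clim, seed=2)
        counts = np.array([len(gt.fire_years_by_plot[p])
                           for p in lan["plot_id"]])
        d = lan["dist_habitation_m"].to_numpy()
        assert np.corrcoef(d, counts)[0, 1] < -0.3

    def test_no_human_fires_after_cessation(self):
        cfg = SyntheticConfig()
        clim = simulate_climate(cfg, seed=0)
        lan = simulate_landscape(cfg, seed=1)
        late = 0
        for s in range(5):
            gt = simulate_fires(lan, cfg, clim, seed=s)
            late += sum(
                y > cfg.human_end_year
                for ys in gt.fire_years_by_plot.values()
                for y in ys
            )
        assert late == 0


class TestTreeRecords:
    def test_lossless_limit_recovers_every_fire_year(self):
        cfg = SyntheticConfig(p_scar=1.0, trees_per_plot=2,
                              pith_range=(1200, 1250))
        clim = simulate_climate(cfg, seed=0)
        lan = simulate_landscape(cfg, seed=1)
        gt = simulate_fires(lan, cfg, clim, seed=2)
        coll, _ = simulate_tree_records(gt, lan, cfg, seed=3)
        chron = detect_fire_events(coll, min_trees=2)
        assert set(chron.fire_years) == set(gt.fire_years)

    def test_zero_recording_probability_empty_record(self):
        cfg = SyntheticConfig(p_scar=0.0)
        clim = simulate_climate(cfg, seed=0)
        lan = simulate_landscape(cfg, seed=1)
        gt = simulate_fires(lan, cfg, clim, seed=2)
        coll, _ = simulate_tree_records(gt, lan, cfg, seed=3)
        assert scar_summary(coll)["n_scars"] == 0
        with pytest.raises(ValueError):
            detect_fire_events(coll, 2).period_start

    def test_detected_events_subset_of_true_years(self):
        ds = simulate_dataset(seed=11)
        chron = detect_fire_events(ds.collection, 2)
        assert set(chron.fire_years) <= set(ds.ground_truth.fire_years)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_default_totals_near_emulation_targets(self, seed):
        """Record size within a factor two of ~45 trees / ~99 scars / ~16
        events under default rates."""
        ds = simulate_dataset(seed=seed)
        s = scar_summary(ds.collection)
        chron = detect_fire_events(ds.collection, 2)
        chron = verify_single_scar_events(
            ds.collection, chron, ds.establishment_by_plot
        )
        assert 45 / 2 <= s["n_scarred_trees"] <= 45 * 2
        assert 99 / 2 <= s["n_scars"] <= 99 * 2
        assert 16 / 2 <= len(chron) <= 16 * 2


class TestEndToEnd:
    def test_dataset_determinism(self):
        from firesync import write_fhx

        a = simulate_dataset(seed=5)
        b = simulate_dataset(seed=5)
        assert write_fhx(a.collection) == write_fhx(b.collection)
        assert a.plots.equals(b.plots)
        assert a.ground_truth.fire_years == b.ground_truth.fire_years

    def test_glm_recovers_negative_distance_slope(self):
        ds = simulate_dataset(seed=3)
        res = select_models(ds.plots, "scar_abundance")
        avg = res.average()
        assert avg.coefficients.get("dist_habitation", 0.0) < 0

    def test_bea_recovers_planted_drought_lag(self):
        ds = simulate_dataset(seed=3)
        chron = detect_fire_events(ds.collection, 2)
        pdsi = ds.climate["PDSI"]
        from firesync import select_extreme_years

        period = (pdsi.start, 1893)
        dry = select_extreme_years(pdsi, "-", k=50, period=period)
        fires = [y for y in chron.fire_years if period[0] <= y <= period[1]]
        res = mc_envelopes(fires, dry.event_years, period, t_max=10,
                           n_reps=500, seed=9)
        labels = res.classification(0.95)
        assert "synchronous" in labels[1:]
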