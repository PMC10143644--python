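import numpy as np
import pandas as pd
import pytest

from redgepheno.env_metrics import et_daily
from redgepheno.rgb_index import RGBView, hue_index, segment_rgb
from redgepheno.synthetic_scene import (
    ETModel,
    ExperimentDesign,
    RedEdgeModel,
    SceneConfig,
    default_wavelengths,
    generate_hypercube,
    generate_rgb_views,
    generate_weather,
    generate_weight_series,
)


class TestRedEdgeModel:
    def test_logistic_monotone_nondecreasing(self, wavelengths):
        model = RedEdgeModel(noise_sd=0.0)
        refl = model.reflectance(wavelengths)
        assert np.all(np.diff(refl) >= 0)
        assert refl[0] == pytest.approx(model.r_red, abs=0.01)
        assert refl[-1] == pytest.approx(model.r_nir, abs=0.01)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            RedEdgeModel(r_red=0.6, r_nir=0.5)
        with pytest.raises(ValueError):
            RedEdgeModel(lambda_infl=600.0)
        with pytest.raises(ValueError):
            RedEdgeModel(rate=0.0)

    def test_attenuation_scales_rate_and_nir(self):
        base = RedEdgeModel()
        att = base.attenuate(0.3)
        assert att.rate == pytest.approx(0.7 * base.rate)
        assert att.r_nir == pytest.approx(0.7 * base.r_nir)
        assert att.max_slope < base.max_slope


class TestGenerateHypercube:
    def test_camera_grid_has_69_bands_and_750nm_at_band_41(self):
        wl = default_wavelengths()
        assert len(wl) == 69
        assert wl[40] == 750.0  # band 41, 1-based
        cube, _ = generate_hypercube(
            SceneConfig(frame_rows=32, frame_cols=32, panel_roi=(0, 0, 6, 6)),
            RedEdgeModel(noise_sd=0.0),
        )
        assert cube.n_bands == 69

    def test_noiseless_plateau_pixel(self, small_config, noiseless_model):
        cube, truth = generate_hypercube(small_config, noiseless_model, 0.0)
        r, c = np.argwhere(truth.illuminated_mask)[0]
        expected = truth.red_edge.reflectance(cube.wavelengths)
        illuminant = cube.data[:, 0, 30] / small_config.background_reflectance
        np.testing.assert_allclose(cube.data[:, r, c], expected * illuminant, rtol=1e-9)
        # at 820 nm the logistic has reached (near) the NIR plateau
        assert cube.data[-1, r, c] / illuminant[-1] == pytest.approx(
            truth.red_edge.r_nir, rel=1e-3
        )

    def test_determinism(self, small_config):
        a, _ = generate_hypercube(small_config, RedEdgeModel(), 0.2, seed=77)
        b, _ = generate_hypercube(small_config, RedEdgeModel(), 0.2, seed=77)
        np.testing.assert_array_equal(a.data, b.data)

    def test_panel_pixels_flat(self, small_config, noiseless_model):
        cube, _ = generate_hypercube(small_config, noiseless_model, 0.0)
        r0, c0, r1, c1 = small_config.panel_roi
        panel_refl = cube.data[:, r0:r1, c0:c1] / cube.data[:, r0, c0][:, None, None]
        np.testing.assert_allclose(panel_refl, 1.0, rtol=1e-12)

    def test_shaded_pixels_preserve_spectral_shape(self, small_config, noiseless_model):
        cube, truth = generate_hypercube(small_config, noiseless_model, 0.0, seed=4)
        shaded = truth.plant_mask & ~truth.illuminated_mask
        r, c = np.argwhere(shaded)[0]
        ri, ci = np.argwhere(truth.illuminated_mask)[0]
        ratio = cube.data[:, r, c] / cube.data[:, ri, ci]
        assert np.ptp(ratio) < 1e-9  # multiplicative shading: constant ratio
        assert ratio[0] < 1.0

    def test_truth_masks_nested(self, small_config, noiseless_model):
        _, truth = generate_hypercube(small_config, noiseless_model, 0.3)
        assert np.all(truth.plant_mask[truth.illuminated_mask])

    def test_overlapping_panel_rejected(self):
        cfg = SceneConfig(
            frame_rows=32, frame_cols=32, panel_roi=(0, 0, 28, 28), plant_fraction=0.2
        )
        with pytest.raises(ValueError, match="overlap"):
            generate_hypercube(cfg, RedEdgeModel())


class TestGenerateRGBViews:
    def test_pure_green_at_zero_stress_zero_jitter(self):
        views = generate_rgb_views(None, 0.0, seed=1, hue_sigma=0.0, area_cv=0.0)
        img, mask = views["TV"]
        hue = hue_index(RGBView(img, "TV", 1.0), mask)
        assert hue == pytest.approx(120.0, abs=1e-9)
        r, g, b = img[mask][0]
        assert r == b < g  # pure green hue

    def test_mask_areas_match_configuration(self):
        areas = (500, 700, 600)
        views = generate_rgb_views(None, 0.0, seed=1, base_areas=areas, area_cv=0.0)
        total = sum(int(views[v][1].sum()) for v in ("TV", "SV0", "SV90"))
        assert total == sum(areas)

    def test_stress_lowers_mean_hue(self):
        calm = generate_rgb_views(None, 0.0, seed=9)
        hot = generate_rgb_views(None, 1.0, seed=9)
        hue = lambda v: hue_index(RGBView(v[0], "TV", 1.0), v[1])
        assert hue(hot["TV"]) < hue(calm["TV"])

    def test_stress_shrinks_masks(self):
        calm = generate_rgb_views(None, 0.0, seed=9, area_cv=0.0)
        hot = generate_rgb_views(None, 1.0, seed=9, area_cv=0.0)
        for v in ("TV", "SV0", "SV90"):
            assert hot[v][1].sum() < calm[v][1].sum()

    def test_background_is_near_black(self):
        views = generate_rgb_views(None, 0.0, seed=1)
        img, mask = views["SV0"]
        assert img[~mask].max() <= 25

    def test_segmentation_recovers_generated_mask(self):
        views = generate_rgb_views(None, 0.3, seed=5, hue_sigma=0.0)
        img, mask = views["SV90"]
        recovered = segment_rgb(RGBView(img, "SV90", 1.0))
        np.testing.assert_array_equal(recovered, mask)

    def test_invalid_stress_rejected(self):
        with pytest.raises(ValueError):
            generate_rgb_views(None, 1.5, seed=0)


class TestGenerateWeightSeries:
    def design(self, **kw):
        kw.setdefault("genotypes", ("770P",))
        kw.setdefault("stress_effect", (0.45,))
        kw.setdefault("replicates", 2)
        kw.setdefault("seed", 3)
        return ExperimentDesign(**kw)

    def test_full_restoration_keeps_weight_constant(self):
        model = ETModel(base_et_g=500.0, growth_per_day=0.0, noise_sd_g=0.0)
        w = generate_weight_series(self.design(), model)
        control = w[w.treatment == "control"]
        for _, grp in control.groupby("pot_id"):
            assert np.ptp(grp.weight_g.to_numpy()) < 1e-9

    def test_partial_restoration_declines_at_30pct_of_et(self):
        model = ETModel(
            base_et_g=500.0, growth_per_day=0.0, noise_sd_g=0.0,
            stress_et_factor=1.0, refill_on_recovery=False,
        )
        w = generate_weight_series(self.design(), model)
        pot = w[w.treatment == "stressed"].groupby("pot_id").get_group(
            w[w.treatment == "stressed"].pot_id.iloc[0]
        )
        deltas = -np.diff(pot.weight_g.to_numpy())
        dates = pot.date.to_numpy()[:-1]
        design = self.design()
        in_stress = np.array(
            [any(s <= pd.Timestamp(d) < e for s, e in design.stress_windows()) for d in dates]
        )
        pot_et = pot.water_added_g.to_numpy()[0] / 0.7  # constant actual ET
        np.testing.assert_allclose(deltas[in_stress], 0.3 * pot_et, rtol=1e-9)
        np.testing.assert_allclose(deltas[~in_stress], 0.0, atol=1e-9)

    def test_stressed_et_below_control_every_replicate(self):
        design = ExperimentDesign(
            genotypes=("770P", "990P"), stress_effect=(0.45, 0.45), replicates=6, seed=0
        )
        w = generate_weight_series(design)
        et = et_daily(w).merge(
            w[["pot_id", "treatment", "date"]], on=["pot_id", "date"]
        )
        for start, end in design.stress_windows():
            window = et[(et.date >= start) & (et.date < end)]
            by_pot = window.groupby(["treatment", "pot_id"]).et_g.mean()
            assert by_pot["stressed"].max() < by_pot["control"].min()

    def test_weights_positive_and_deterministic(self):
        a = generate_weight_series(self.design(), seed=5)
        b = generate_weight_series(self.design(), seed=5)
        pd.testing.assert_frame_equal(a, b)
        assert (a.weight_g > 0).all()

    def test_negative_et_parameters_rejected(self):
        with pytest.raises(ValueError):
            ETModel(base_et_g=-1.0)


class TestGenerateWeather:
    def test_record_count(self):
        w = generate_weather(3, seed=0)
        assert len(w) == 3 * 96
        assert w.timestamp.dt.normalize().nunique() == 3

    def test_flat_profile(self):
        w = generate_weather(
            2, seed=0, t_amp_c=0.0, rh_amp_pct=0.0, t_trend_c_per_day=0.0,
            noise_sd_t=0.0, noise_sd_rh=0.0, t_mean_c=25.0, rh_mean_pct=50.0,
        )
        assert (w.t_c == 25.0).all()
        assert (w.rh_pct == 50.0).all()

    def test_determinism_and_ranges(self):
        a = generate_weather(5, seed=8)
        b = generate_weather(5, seed=8)
        pd.testing.assert_frame_equal(a, b)
        assert (a.rh_pct > 0).all() and (a.rh_pct <= 100).all()
        assert a.t_c.between(5, 45).all()
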