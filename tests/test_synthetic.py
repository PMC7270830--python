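import numpy as np
import pandas as pd
import pytest

from phenorow.biomass import SeasonModel, predict_dmy
from phenorow.calibration import compute_ndvi
from phenorow.synthetic import (
    LayoutError,
    SensorRig,
    TrialLayout,
    default_path,
    generate_layout,
    render_ortho,
    simulate_harvest,
    simulate_height_track,
)


class TestLayout:
    def test_default_counts(self):
        lay = TrialLayout()
        assert lay.n_plots == 500
        assert lay.n_rows == 1500
        assert lay.n_plants == 48000

    def test_default_generation_produces_all_plants(self):
        plants, rows, plots = generate_layout(TrialLayout(rng_seed=1))
        assert (len(plots), len(rows), len(plants)) == (500, 1500, 48000)
        assert plants["plant_id"].is_unique

    def test_minimal_layout_single_plant_at_half_spacings(self):
        lay = TrialLayout(
            n_entries=1, n_reps=1, n_blocks=1, rows_per_plot=1,
            plants_per_row=1, plot_width=0.6, rng_seed=0,
        )
        plants, rows, plots = generate_layout(lay)
        assert len(plants) == 1
        p = plants.iloc[0]
        assert p["x"] == pytest.approx(lay.margin + 0.5 * lay.row_spacing)
        assert p["y"] == pytest.approx(lay.margin + 0.5 * lay.plant_spacing)

    def test_rcbd_each_entry_once_per_block(self):
        lay = TrialLayout(n_entries=2, n_reps=2, n_blocks=2, rng_seed=3)
        plants, rows, plots = generate_layout(lay)
        assert len(plots) == 4
        for _, block in plots.groupby("block"):
            assert sorted(block["entry"]) == [1, 2]

    def test_seed_determinism_and_scoping(self):
        lay = TrialLayout(n_entries=2, n_reps=2, n_blocks=2, rng_seed=5)
        a, _, _ = generate_layout(lay)
        b, _, _ = generate_layout(lay)
        pd.testing.assert_frame_equal(a, b)
        c, _, _ = generate_layout(
            TrialLayout(n_entries=2, n_reps=2, n_blocks=2, rng_seed=6)
        )
        # different seed: same geometry, different trait draws
        np.testing.assert_allclose(c["x"], a["x"])
        np.testing.assert_allclose(c["y"], a["y"])
        assert not np.allclose(c["true_ndvi"], a["true_ndvi"])

    def test_invalid_layouts_name_the_constraint(self):
        with pytest.raises(LayoutError, match="plant_spacing"):
            TrialLayout(plants_per_row=40)
        with pytest.raises(LayoutError, match=">= 1"):
            TrialLayout(n_entries=0)
        with pytest.raises(LayoutError, match="n_reps == n_blocks"):
            TrialLayout(n_reps=5)

    def test_count_conservation(self):
        lay = TrialLayout(n_entries=3, n_reps=2, n_blocks=2, rng_seed=0)
        plants, rows, plots = generate_layout(lay)
        assert len(plants) == lay.rows_per_plot * lay.plants_per_row * len(plots)
        per_row = plants.groupby("row_id").size()
        assert (per_row == lay.plants_per_row).all()


class TestRender:
    def test_blob_centre_pixel_carries_true_ndvi(
        self, small_layout, small_truth, small_render
    ):
        plants, _, _ = small_truth
        _, truth, _, _ = small_render
        cols = np.rint(plants["x"] / small_layout.gsd).astype(int)
        rows = np.rint(plants["y"] / small_layout.gsd).astype(int)
        np.testing.assert_allclose(
            truth.data[0][rows, cols], plants["true_ndvi"], atol=1e-6
        )

    def test_reflectance_render_ndvi_equals_truth(
        self, small_layout, small_truth, small_render
    ):
        raster, truth, _, _ = small_render
        ndvi = compute_ndvi(raster.band("red"), raster.band("nir"))
        np.testing.assert_allclose(ndvi, truth.data[0], atol=1e-6)

    def test_panel_dn_inverts_gain(self, small_layout, small_truth):
        plants, _, _ = small_truth
        raster, _, panels, _ = render_ortho(
            plants, small_layout, bands=("red", "nir"), dn_gain=0.1, dn_offset=0.0
        )
        p22 = [p for p in panels if p.reflectance_pct == 22.0][0]
        c0, r0, c1, r1 = p22.box_px
        assert float(raster.band("red")[r0:r1, c0:c1].mean()) == pytest.approx(220.0)

    def test_soil_ndvi_below_every_plant(self, small_truth, small_render):
        plants, _, _ = small_truth
        assert plants["true_ndvi"].min() > 0.15  # soil upper bound

    def test_raster_spans_plot_grid(self, small_layout, small_render):
        raster, _, _, _ = small_render
        fx0, fy0, fx1, fy1 = small_layout.field_bbox()
        assert raster.shape[1] >= (fx1 - fx0) / small_layout.gsd
        assert raster.shape[0] >= (fy1 - fy0) / small_layout.gsd

    def test_oversized_render_rejected(self, small_layout, small_truth):
        plants, _, _ = small_truth
        with pytest.raises(LayoutError, match="max_pixels"):
            render_ortho(plants, small_layout, max_pixels=1000)

    def test_gcps_outside_field_and_nine_of_them(self, small_layout, small_render):
        _, truth, _, gcps = small_render
        assert len(gcps) == 9
        assert (gcps["role"] == "corner").sum() == 4
        fx0, fy0, fx1, fy1 = small_layout.field_bbox()
        g = small_layout.gsd
        # no marker pixel (NDVI exactly 0) inside the trial area
        c0, r0 = int(fx0 / g), int(fy0 / g)
        c1, r1 = int(fx1 / g), int(fy1 / g)
        assert (truth.data[0][r0:r1, c0:c1] == 0).sum() == 0

    def test_render_determinism(self, small_layout, small_truth):
        plants, _, _ = small_truth
        a, _, _, _ = render_ortho(plants, small_layout, bands=("red",), seed=9)
        b, _, _, _ = render_ortho(plants, small_layout, bands=("red",), seed=9)
        np.testing.assert_array_equal(a.data, b.data)


class TestHeightTrack:
    def small(self):
        lay = TrialLayout(
            n_entries=1, n_reps=1, n_blocks=1, rows_per_plot=1,
            plants_per_row=4, plot_width=0.6, rng_seed=2,
        )
        plants, _, _ = generate_layout(lay)
        return lay, plants

    def test_range_over_plant_and_soil(self):
        lay, plants = self.small()
        plants = plants.copy()
        plants["true_height_cm"] = 15.0
        rig = SensorRig(lateral_offsets=(0.0, -0.3, 0.3, -0.6, 0.6, -0.9))
        track = simulate_height_track(plants, lay, rig=rig)
        over = track[track.sensor_index == 0]
        # sensor 0 rides the row line: over a plant range = 0.6 - 0.15
        assert (np.isclose(over["range_m"], 0.45) | np.isclose(over["range_m"], 0.6)).all()
        assert np.isclose(over["range_m"], 0.45).any()
        soil = track[track.sensor_index == 3]
        np.testing.assert_allclose(soil["range_m"], 0.6)

    def test_determinism_with_noise(self):
        lay, plants = self.small()
        rig = SensorRig(range_noise_sd=0.01)
        a = simulate_height_track(plants, lay, rig=rig, seed=4)
        b = simulate_height_track(plants, lay, rig=rig, seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_path_outside_field_warns_and_empty(self):
        lay, plants = self.small()
        far = [((500.0, 0.0), (500.0, 10.0))]
        with pytest.warns(UserWarning, match="never enters"):
            track = simulate_height_track(plants, lay, path=far)
        assert track.empty

    def test_default_path_covers_every_row(self):
        lay = TrialLayout(n_entries=2, n_reps=2, n_blocks=2, rng_seed=0)
        assert len(default_path(lay)) == lay.rows_per_block


class TestHarvest:
    def test_zero_noise_equals_model(self):
        lay = TrialLayout(n_entries=2, n_reps=2, n_blocks=2, rng_seed=1)
        plants, _, _ = generate_layout(lay)
        per_plant, per_plot = simulate_harvest(plants, "winter2018", noise_sd=0.0)
        want = predict_dmy(
            plants["true_ndvi"] ** 2 * plants["true_height_cm"], "winter2018"
        )
        np.testing.assert_allclose(per_plant["measured_g"], want)

    def test_plot_sum_unit_conversion(self):
        lay = TrialLayout(n_entries=2, n_reps=2, n_blocks=2, rng_seed=1)
        plants, _, _ = generate_layout(lay)
        per_plant, per_plot = simulate_harvest(plants, "winter2018", noise_sd=0.0)
        merged = per_plant.groupby("plot_id")["measured_g"].sum() / 1000.0
        got = per_plot.set_index("plot_id")["measured_kg"]
        np.testing.assert_allclose(got, merged[got.index])

    def test_winter_at_zero_predictor(self):
        lay = TrialLayout(
            n_entries=1, n_reps=1, n_blocks=1, rows_per_plot=1,
            plants_per_row=1, plot_width=0.6, rng_seed=0,
        )
        plants, _, _ = generate_layout(lay)
        plants = plants.copy()
        plants["true_ndvi"] = 0.0
        per_plant, _ = simulate_harvest(plants, "winter2018", noise_sd=0.0)
        assert per_plant.loc[0, "measured_g"] == pytest.approx(-4.62)

    def test_unknown_season_lists_labels(self):
        lay = TrialLayout(n_entries=2, n_reps=2, n_blocks=2, rng_seed=1)
        plants, _, _ = generate_layout(lay)
        with pytest.raises(ValueError, match="late-spring2018_1"):
            simulate_harvest(plants, "summer2018")

    def test_truncation_recorded(self):
        lay = TrialLayout(n_entries=2, n_reps=2, n_blocks=2, rng_seed=1)
        plants = generate_layout(lay)[0].copy()
        plants["true_ndvi"] = 0.0
        per_plant, _ = simulate_harvest(
            plants, "winter2018", noise_sd=0.0, truncate_negative=True
        )
        assert (per_plant["measured_g"] >= 0).all()
        assert per_plant.attrs["truncate_negative"] is True
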