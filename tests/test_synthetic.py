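import numpy as np
import pandas as pd
import pytest
import tifffile

from geledge.conditions import PRESETS, ConditionParams, condition_at_depth
from geledge.synthetic import (
    ImagingConfig,
    apply_drift,
    make_drift,
    render_plane,
    render_time_lapse,
    sample_cell_shapes,
    simulate_tracks,
    tracks_to_table,
    write_dataset,
)

LOW = PRESETS["40pct_low"]
HIGH = PRESETS["40pct_high"]


class TestSampleCellShapes:
    def test_pooled_moments_match_printed_statistics(self):
        df = sample_cell_shapes(LOW, 10_000, seed=3)
        assert df.area_um2.mean() == pytest.approx(1340.0, rel=0.02)
        assert df.area_um2.std() == pytest.approx(470.0, rel=0.05)
        assert df.aspect_ratio.mean() == pytest.approx(10.4, rel=0.03)
        assert df.aspect_ratio.std() == pytest.approx(7.3, rel=0.05)

    def test_single_component_when_no_spindle_cells(self):
        df = sample_cell_shapes(HIGH, 10_000, seed=4)
        assert not df.spindle.any()
        assert df.aspect_ratio.mean() == pytest.approx(1.6, rel=0.03)
        assert df.aspect_ratio.min() >= 1.0
        assert df.area_um2.min() > 0.0

    def test_same_seed_reproduces_samples(self):
        a = sample_cell_shapes(LOW, 100, seed=7)
        b = sample_cell_shapes(LOW, 100, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_infeasible_mixture_rejected(self):
        with pytest.raises(ValueError, match="infeasible mixture"):
            sample_cell_shapes(LOW, 10, seed=0, separation=3.0)


class TestDepthProfile:
    def test_interface_and_bulk_limits(self):
        at0 = condition_at_depth(LOW, HIGH, 100.0, 0.0)
        far = condition_at_depth(LOW, HIGH, 100.0, 1e6)
        assert at0.area_mean == pytest.approx(LOW.area_mean)
        assert far.area_mean == pytest.approx(HIGH.area_mean)

    def test_half_decay_value(self):
        z = 100.0 * np.log(2.0)
        mid = condition_at_depth(LOW, HIGH, 100.0, z)
        assert mid.area_mean == pytest.approx(870.0, rel=1e-6)

    def test_positive_decay_length_required(self):
        with pytest.raises(ValueError):
            condition_at_depth(LOW, HIGH, 0.0, 10.0)


class TestRenderPlane:
    def test_noiseless_disk_pixel_area(self):
        r = 12.0
        shapes = pd.DataFrame({"area_um2": [np.pi * r**2], "aspect_ratio": [1.0]})
        config = ImagingConfig(image_shape=(256, 256), noise_sd=0.0)
        image, truth = render_plane(shapes, config, seed=0)
        foreground = int((image > 500).sum())
        assert foreground == pytest.approx(np.pi * r**2, abs=2 * np.pi * r)
        assert len(truth) == 1

    def test_empty_shape_list_gives_pure_noise(self):
        config = ImagingConfig(image_shape=(64, 64), noise_sd=10.0)
        image, truth = render_plane(pd.DataFrame({"area_um2": [], "aspect_ratio": []}),
                                    config, seed=0)
        assert truth.empty
        assert image.mean() == pytest.approx(100.0, abs=5.0)

    def test_rendered_ellipse_roundtrips_through_moments(self):
        from geledge.morphometry import measure_plane

        shapes = pd.DataFrame({"area_um2": [800.0], "aspect_ratio": [4.0]})
        config = ImagingConfig(image_shape=(256, 256), noise_sd=0.0)
        image, _ = render_plane(shapes, config, seed=5)
        rec = measure_plane(image, 0.0)
        assert len(rec) == 1
        assert rec.aspect_ratio[0] == pytest.approx(4.0, rel=0.05)
        assert rec.area_um2[0] == pytest.approx(800.0, rel=0.05)

    def test_unplaceable_cell_raises(self):
        shapes = pd.DataFrame({"area_um2": [1e6], "aspect_ratio": [1.0]})
        config = ImagingConfig(image_shape=(128, 128), noise_sd=0.0)
        with pytest.raises(RuntimeError, match="could not place"):
            render_plane(shapes, config, seed=0)


class TestSimulateTracks:
    config = ImagingConfig(image_shape=(800, 800))

    def test_constant_speed_gives_exact_path_length(self):
        params = ConditionParams("const", 100, 1, 1.5, 0.1,
                                 speed_mean=30.0, speed_sd=0.0)
        tracks = simulate_tracks(params, 4, self.config, persistence=0.5, seed=2)
        for t in tracks:
            assert t.positions.shape == (37, 2)
            path = np.linalg.norm(np.diff(t.positions, axis=0), axis=1).sum()
            assert path == pytest.approx(360.0, rel=1e-9)
            assert t.true_speed == pytest.approx(30.0)

    def test_zero_persistence_directions_uncorrelated(self):
        params = ConditionParams("iid", 100, 1, 1.5, 0.1,
                                 speed_mean=20.0, speed_sd=0.0)
        config = ImagingConfig(image_shape=(800, 800), duration=400.0)
        track = simulate_tracks(params, 1, config, persistence=0.0, seed=3)[0]
        steps = np.diff(track.positions, axis=0)
        angles = np.arctan2(steps[:, 1], steps[:, 0])
        corr = np.mean(np.cos(np.diff(angles)))
        assert abs(corr) < 0.1  # i.i.d. directions: no persistence

    def test_sampled_speed_mean_near_condition(self):
        tracks = simulate_tracks(LOW, 2000, self.config, seed=4)
        mean = np.mean([t.true_speed for t in tracks])
        assert mean == pytest.approx(29.5, abs=2 * 11.3 / np.sqrt(2000) + 0.16)


class TestDrift:
    config = ImagingConfig(image_shape=(400, 400))

    def test_zero_scale_leaves_tracks_unchanged(self):
        tracks = simulate_tracks(HIGH, 3, self.config, seed=5)
        drifted, drift = apply_drift(tracks, self.config, drift_scale=0.0, seed=6)
        assert np.all(drift == 0.0)
        for a, b in zip(tracks, drifted):
            np.testing.assert_array_equal(a.positions, b.positions)

    def test_constant_drift_accumulates_linearly(self):
        tracks = simulate_tracks(HIGH, 2, self.config, seed=7)
        drift = np.outer(np.arange(37), [1.0, 0.0])
        drifted, _ = apply_drift(tracks, self.config, drift=drift)
        np.testing.assert_allclose(drifted[0].positions[-1] - tracks[0].positions[-1],
                                   [36.0, 0.0])

    def test_subtracting_truth_recovers_originals(self):
        tracks = simulate_tracks(HIGH, 3, self.config, seed=8)
        drifted, drift = apply_drift(tracks, self.config, drift_scale=1.5, seed=9)
        for a, b in zip(tracks, drifted):
            np.testing.assert_allclose(b.positions - drift, a.positions, atol=1e-12)

    def test_drift_is_smooth(self):
        drift = make_drift(self.config, drift_scale=1.0, seed=10)
        assert drift.shape == (37, 2)
        assert np.all(drift[0] == 0.0)
        assert np.abs(np.diff(drift, axis=0)).max() < 5.0


class TestWriteDataset:
    def test_tiff_roundtrip_bit_exact(self, tmp_path):
        config = ImagingConfig(image_shape=(128, 128))
        tracks = simulate_tracks(HIGH, 2, config, seed=11)
        stack = render_time_lapse(tracks, config, seed=12, n_speckles=50)
        table = tracks_to_table(tracks, config)
        written = write_dataset(tmp_path, stacks={"movie": stack},
                                tables={"truth": table}, config=config)
        assert np.array_equal(tifffile.imread(written["movie"]), stack)
        assert len(pd.read_csv(written["truth"])) == len(table)

    def test_seeded_regeneration_byte_identical(self, tmp_path):
        config = ImagingConfig(image_shape=(96, 96))
        paths = []
        for run in ("a", "b"):
            tracks = simulate_tracks(HIGH, 2, config, seed=13)
            stack = render_time_lapse(tracks, config, seed=14, n_speckles=30)
            out = write_dataset(tmp_path / run, stacks={"movie": stack},
                                tables={"truth": tracks_to_table(tracks, config)})
            paths.append(out)
        assert (paths[0]["truth"].read_bytes() == paths[1]["truth"].read_bytes())
        assert np.array_equal(tifffile.imread(paths[0]["movie"]),
                              tifffile.imread(paths[1]["movie"]))
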