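import numpy as np
import pandas as pd
import pytest
from skimage.draw import disk, ellipse

from geledge import morphometry as mm
from geledge.synthetic import ImagingConfig, render_plane


def _image_with(regions, shape=(256, 256), fg=1000.0, bg=100.0, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    img = np.full(shape, bg)
    for rr, cc in regions:
        img[rr, cc] = fg
    if noise:
        img = img + rng.normal(0, noise, shape)
    return img


class TestSegmentPlane:
    def test_blank_noise_image_yields_no_regions(self):
        rng = np.random.default_rng(0)
        img = rng.normal(100.0, 5.0, (128, 128))
        assert mm.segment_plane(img) == []

    def test_counts_match_generator_truth(self):
        shapes = pd.DataFrame({
            "area_um2": [300.0, 450.0, 600.0, 350.0, 500.0,
                         400.0, 550.0, 320.0, 480.0, 380.0],
            "aspect_ratio": [1.5, 2.0, 3.0, 1.2, 2.5, 1.8, 4.0, 1.1, 2.2, 3.5],
        })
        config = ImagingConfig(image_shape=(512, 512), noise_sd=15.0)
        image, truth = render_plane(shapes, config, seed=1)
        regions = mm.segment_plane(image)
        assert len(regions) == len(truth) == 10

    def test_touching_cells_merge_into_one_region(self):
        img = _image_with([disk((100, 100), 15), disk((100, 120), 15)])
        assert len(mm.segment_plane(img)) == 1

    def test_border_touching_and_small_regions_dropped(self):
        img = _image_with([disk((5, 100), 12, shape=(256, 256)),  # clipped at border
                           disk((100, 100), 3),                   # 28 px < 50 µm²
                           disk((180, 180), 12)])
        assert len(mm.segment_plane(img)) == 1


class TestMeasurements:
    def test_area_scales_with_pixel_size_squared(self):
        img = _image_with([disk((64, 64), 10)], shape=(128, 128))
        region = mm.segment_plane(img)[0]
        a1 = mm.measure_area(region, pixel_size=1.0)
        a2 = mm.measure_area(region, pixel_size=0.5)
        assert a2 == pytest.approx(a1 / 4.0)

    def test_disk_aspect_ratio_is_unity(self):
        img = _image_with([disk((64, 64), 20)], shape=(128, 128))
        region = mm.segment_plane(img)[0]
        assert mm.ellipse_aspect_ratio(region) == pytest.approx(1.0, rel=0.02)

    def test_ellipse_aspect_ratio_from_moments(self):
        """Moment AR matches the analytic axis ratio for a well-resolved
        ellipse; at a 5 px minor axis rasterization inflates AR by several
        percent, so only a looser band holds there."""
        img = _image_with([ellipse(120, 120, 10, 40)], shape=(240, 240))
        region = mm.segment_plane(img)[0]
        assert mm.ellipse_aspect_ratio(region) == pytest.approx(4.0, rel=0.05)
        small = _image_with([ellipse(80, 80, 5, 20)], shape=(160, 160))
        region = mm.segment_plane(small)[0]
        assert mm.ellipse_aspect_ratio(region) == pytest.approx(4.0, rel=0.10)

    def test_aspect_ratio_rotation_invariant(self):
        values = []
        for theta in (0.0, 0.4, 1.1):
            img = _image_with([ellipse(150, 150, 30, 60, rotation=theta)],
                              shape=(300, 300))
            values.append(mm.ellipse_aspect_ratio(mm.segment_plane(img)[0]))
        assert max(values) / min(values) < 1.01

    def test_degenerate_region_capped(self):
        img = _image_with([(np.full(30, 64), np.arange(40, 70))])  # 1-px line
        region = mm.segment_plane(img, min_area_um2=10.0)[0]
        assert mm.ellipse_aspect_ratio(region) == 100.0


class TestHeightNormalization:
    def _records(self, zs):
        return pd.DataFrame({"plane_z": zs, "area_um2": 100.0,
                             "aspect_ratio": 2.0, "cell_id": range(len(zs))})

    def test_origin_moves_to_first_populated_plane(self):
        out = mm.normalize_height_origin(self._records([10.0, 10.0, 50.0]))
        assert sorted(out.plane_z.unique()) == [0.0, 40.0]

    def test_idempotent(self):
        once = mm.normalize_height_origin(self._records([5.0, 30.0]))
        twice = mm.normalize_height_origin(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_no_cells_is_an_error(self):
        with pytest.raises(ValueError, match="no cells"):
            mm.normalize_height_origin(self._records([]))


class TestProfileAndFit:
    def test_bin_means(self):
        rec = pd.DataFrame({"plane_z": [10.0, 20.0, 80.0],
                            "area_um2": [2.0, 4.0, 6.0]})
        prof = mm.profile_by_height(rec, bin_edges=(0, 50, 100))
        assert prof["mean"].tolist() == [3.0, 6.0]
        assert prof["n"].tolist() == [2, 1]
        assert prof["sd"].tolist()[1] == 0.0

    def test_empty_bins_omitted_and_bad_edges_rejected(self):
        rec = pd.DataFrame({"plane_z": [10.0], "area_um2": [2.0]})
        prof = mm.profile_by_height(rec, bin_edges=(0, 50, 100, 200))
        assert len(prof) == 1
        with pytest.raises(ValueError, match="strictly increasing"):
            mm.profile_by_height(rec, bin_edges=(0, 0, 10))

    def test_exponential_fit_recovers_noiseless_parameters(self):
        z = np.array([10.0, 40.0, 80.0, 150.0, 300.0, 600.0])
        m = 400.0 + (1340.0 - 400.0) * np.exp(-z / 100.0)
        prof = pd.DataFrame({"z_mid": z, "mean": m, "n": 10, "sd": 1.0})
        fit = mm.fit_exponential_profile(prof)
        assert fit.m0 == pytest.approx(1340.0, rel=0.01)
        assert fit.m_bulk == pytest.approx(400.0, rel=0.01)
        assert fit.decay_length == pytest.approx(100.0, rel=0.01)
        assert not fit.flat

    def test_flat_profile_flagged(self):
        prof = pd.DataFrame({"z_mid": [10.0, 50.0, 100.0, 200.0],
                             "mean": [5.0, 5.0, 5.0, 5.0], "n": 5, "sd": 0.1})
        fit = mm.fit_exponential_profile(prof)
        assert fit.flat
        assert fit.m_bulk == pytest.approx(5.0)
        assert np.isnan(fit.decay_length)

    def test_decay_lengths_rank_ordered(self):
        z = np.array([5.0, 30.0, 70.0, 120.0, 250.0, 500.0])
        fits = []
        for lam in (50.0, 150.0):
            m = 400.0 + 940.0 * np.exp(-z / lam)
            prof = pd.DataFrame({"z_mid": z, "mean": m, "n": 10, "sd": 1.0})
            fits.append(mm.fit_exponential_profile(prof).decay_length)
        assert fits[0] < fits[1]

    def test_too_few_bins_rejected(self):
        prof = pd.DataFrame({"z_mid": [1.0, 2.0], "mean": [3.0, 2.0],
                             "n": 2, "sd": 0.1})
        with pytest.raises(ValueError, match="4 height bins"):
            mm.fit_exponential_profile(prof)
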