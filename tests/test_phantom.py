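import numpy as np
import pytest

from stereonir import (
    MediumModel,
    NoiseModel,
    Tube,
    add_noise,
    apply_medium,
    distance_to_disparity,
    make_capillary_depth_series,
    make_two_layer_phantom,
    medium_for_band,
    project_tube,
    render_capillary,
    render_stereo_pair,
)
from stereonir.profiles import fit_capillary_fwhm


def straight_tube(x=0.0, z=7.5, radius=0.5):
    return Tube(centerline=[[x, -10.0, z], [x, 10.0, z]], radius=radius)


class TestSceneContracts:
    def test_two_layer_phantom_layout(self):
        scene = make_two_layer_phantom()
        assert len(scene.tubes) == 4
        assert all(t.radius * 2 == pytest.approx(1.0) for t in scene.tubes)
        depths = sorted(t.depth for t in scene.tubes)
        assert depths == pytest.approx([7.5, 7.5, 8.5, 8.5])
        assert max(depths) - min(depths) == pytest.approx(1.0)  # layer gap
        assert scene.extent == (40.0, 30.0)

    def test_tube_validation(self):
        with pytest.raises(ValueError):
            Tube(centerline=[[0, 0, 1]], radius=0.5)
        with pytest.raises(ValueError):
            Tube(centerline=[[0, 0, 1], [1, 0, 1]], radius=-1)


class TestProjection:
    def test_chord_profile_fwhm_is_radius_times_sqrt3(self):
        # half maximum of 2*sqrt(r^2-x^2) sits at |x| = r*sqrt(3)/2
        med = MediumModel(mu_eff=0.0, psf_fwhm_at_1mm=0.0, psf_fwhm_slope=0.0)
        img = render_capillary(1.0, med, pixel_size_mm=0.01, shape=(400, 8), radius_mm=0.55)
        prof = img[:, 4]
        above = np.where(prof >= 0.5 * prof.max())[0]
        width_mm = (above[-1] - above[0] + 1) * 0.01
        assert width_mm == pytest.approx(0.55 * np.sqrt(3), abs=0.02)

    def test_rendered_disparity_matches_triangulation(self, rig):
        """Sub-pixel centroid separation of the projected tube equals the
        b*f/Z prediction to better than 0.05 px (pre-blur, pre-noise)."""
        tube = straight_tube(x=0.0, z=7.5)
        left = project_tube(tube, rig, "left")
        right = project_tube(tube, rig, "right")
        cols = np.arange(left.shape[1])
        row = slice(200, 312)
        cl = (left[row] * cols).sum() / left[row].sum()
        cr = (right[row] * cols).sum() / right[row].sum()
        expected_px = distance_to_disparity(450.0 + 7.5, rig) / rig.camera.pixel_pitch_mm
        assert cl - cr == pytest.approx(expected_px, abs=0.05)

    def test_depth_gap_disparity_difference(self, rig):
        # d(Z) - d(Z + 1 mm) ~ b f dZ / Z^2 ~ 0.345 px at the modelled rig
        d1 = distance_to_disparity(457.5, rig) / rig.camera.pixel_pitch_mm
        d2 = distance_to_disparity(458.5, rig) / rig.camera.pixel_pitch_mm
        assert d1 - d2 == pytest.approx(40 * 35 * 1.0 / 458**2 / 0.02, rel=0.01)

    def test_out_of_field_tube_warns_and_is_empty(self, rig):
        tube = straight_tube(x=500.0)
        with pytest.warns(UserWarning):
            img = project_tube(tube, rig, "left")
        assert not img.any()


class TestMedium:
    def test_identity_medium_is_identity(self):
        med = MediumModel(mu_eff=0.0, psf_fwhm_at_1mm=0.0, psf_fwhm_slope=0.0)
        rng = np.random.default_rng(0)
        img = rng.random((32, 32))
        out = apply_medium(img, 1.0, med)
        assert np.allclose(out, img)

    @pytest.mark.parametrize("band, half_depth", [("LP1100", 4.0), ("LP1300", 2.0)])
    def test_half_intensity_depths_of_shipped_bands(self, band, half_depth):
        med = medium_for_band(band)
        img = np.ones((16, 16))
        ref = apply_medium(img, 1.0, med).sum()
        att = apply_medium(img, half_depth, med).sum()
        assert att / ref == pytest.approx(0.5, rel=1e-6)

    def test_attenuation_log_linear(self):
        med = medium_for_band("LP1300")
        depths = np.linspace(1, 6, 11)
        vals = np.array([med.attenuation(z) for z in depths])
        slope, intercept = np.polyfit(depths, np.log(vals), 1)
        resid = np.log(vals) - (slope * depths + intercept)
        r2 = 1 - resid.var() / np.log(vals).var()
        assert slope == pytest.approx(-med.mu_eff, rel=1e-9)
        assert r2 > 0.999

    def test_psf_fwhm_nondecreasing(self):
        med = medium_for_band("LP1100")
        fw = [med.psf_fwhm(z) for z in np.linspace(1, 6, 20)]
        assert np.all(np.diff(fw) > 0)


class TestNoise:
    def test_fixed_seed_reproducible(self):
        img = np.full((64, 64), 5000.0)
        a = add_noise(img, NoiseModel(seed=42))
        b = add_noise(img, NoiseModel(seed=42))
        assert np.array_equal(a, b)
        c = add_noise(img, NoiseModel(seed=43))
        assert not np.array_equal(a, c)

    def test_flat_field_variance_matches_model(self):
        img = np.full((100, 100), 8000.0)
        noise = NoiseModel(photon_scale=0.25, read_noise_sd=60.0, seed=1)
        out = add_noise(img, noise).astype(float)
        expected = 8000.0 / 0.25 + 60.0**2
        assert out.var() == pytest.approx(expected, rel=0.05)
        assert out.mean() == pytest.approx(8000.0, rel=0.01)

    def test_noise_free_limit_quantises_input(self):
        img = np.full((16, 16), 1234.4)
        out = add_noise(img, NoiseModel(photon_scale=1e7, read_noise_sd=0.0, seed=0))
        assert np.all(out == 1234)


class TestCapillarySeries:
    def test_peak_intensity_monotonically_decreasing(self):
        series = make_capillary_depth_series(range(1, 7), medium_for_band("LP1300"))
        peaks = [img.max() for img in series]
        assert np.all(np.diff(peaks) < 0)

    def test_lp1100_fwhm_strictly_increasing(self):
        series = make_capillary_depth_series(range(1, 7), medium_for_band("LP1100"))
        fwhm = [fit_capillary_fwhm(img, 0.1).fwhm for img in series]
        assert np.all(np.diff(fwhm) > 0)

    def test_lp1300_fwhm_stays_within_twofold(self):
        series = make_capillary_depth_series([1, 6], medium_for_band("LP1300"))
        fwhm = [fit_capillary_fwhm(img, 0.1).fwhm for img in series]
        assert fwhm[1] / fwhm[0] < 2.0

    def test_depths_must_be_positive(self):
        with pytest.raises(ValueError):
            make_capillary_depth_series([0.0, 1.0], medium_for_band("LP1300"))


class TestStereoRendering:
    def test_canonical_pair_shows_four_tubes_and_truth_is_consistent(self, config):
        scene = make_two_layer_phantom()
        left, right, truth = render_stereo_pair(
            scene, config.rig(), config.medium(), NoiseModel(seed=0)
        )
        assert left.shape == (512, 640) and right.shape == (512, 640)
        assert truth["labels"].max() == 4
        # every tube leaves a bright footprint in both views
        for img in (left, right):
            assert (img > 0.2 * img.max()).sum() > 4 * 300
        assert np.array_equal(truth["mask"], truth["labels"] > 0)
        assert np.isfinite(truth["depth"][truth["mask"]]).all()

    def test_render_bit_reproducible(self, config):
        scene = make_two_layer_phantom()
        a = render_stereo_pair(scene, config.rig(), config.medium(), NoiseModel(seed=3))
        b = render_stereo_pair(scene, config.rig(), config.medium(), NoiseModel(seed=3))
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])
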