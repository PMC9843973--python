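"""AFM-IR leveling, artifact repair, registration, normalisation and ratios."""

import numpy as np
import pytest

from mycoftir.afmir_pipeline import (
    PointSpectrumGroup,
    RigidTransform,
    ThickSampleError,
    apply_rigid,
    correct_mapset,
    level_topography,
    log_ratio_maps,
    normalize_absorption,
    preprocess_point_spectra,
    register_maps,
    repair_contact_loss,
    rescale_topography,
    segment_afmir,
)
from mycoftir.spectral_core import LaserPowerSpectrum, WavenumberAxis
from mycoftir.synthetic_data import AFMIRSceneParams, Droplet, synth_afmir_scene


def _grid(n=64):
    y, x = np.mgrid[0:n, 0:n].astype(float)
    return y, x


class TestLeveling:
    def test_pure_plane_removed(self):
        y, x = _grid()
        plane = 2.0 * x / 63 + 3.0 * y / 63
        np.testing.assert_allclose(level_topography(plane), 0.0, atol=1e-9)

    def test_plane_plus_line_offsets_removed(self):
        y, x = _grid()
        rng = np.random.default_rng(0)
        topo = 0.5 * x / 63 + rng.uniform(-0.01, 0.01, (64, 1))
        np.testing.assert_allclose(level_topography(topo), 0.0, atol=1e-9)

    def test_droplet_bump_preserved(self):
        y, x = _grid()
        bump = 0.1 * np.exp(-(((y - 30) / 5.0) ** 2 + ((x - 40) / 5.0) ** 2))
        topo = bump + 1.5 * x / 63 - 0.8 * y / 63
        out = level_topography(topo)
        off_bump = bump < 1e-4
        assert np.sqrt(np.mean(out[off_bump] ** 2)) < 0.001  # < 1% of bump height
        assert out.max() == pytest.approx(0.1, rel=0.05)

    def test_order_too_high_rejected(self):
        with pytest.raises(ValueError):
            level_topography(np.zeros((3, 3)), poly_order=5)


class TestContactLossRepair:
    def test_dropout_in_uniform_map_repaired(self):
        rng = np.random.default_rng(1)
        a = 1.0 + rng.normal(0, 0.01, (16, 16))
        a[7, 8] = 0.0
        out = repair_contact_loss(a)
        assert out[7, 8] == pytest.approx(1.0, abs=0.05)

    def test_clean_constant_map_unchanged(self):
        a = np.full((10, 10), 0.8)
        np.testing.assert_array_equal(repair_contact_loss(a), a)

    def test_planted_dropout_segments_repaired(self):
        params = AFMIRSceneParams(seed=5, drift={}, tilt=(0, 0), line_offset_sd=0.0,
                                  contact_loss_rate=0.01)
        mapset, truth = synth_afmir_scene(params)
        for w in (1600.0, 1708.0, 1742.0):
            loss = truth["contact_loss"][w]
            if not loss.any():
                continue
            raw = mapset.get(w, "absorption")
            repaired = repair_contact_loss(raw)
            power = mapset.laser_power.at(w)
            target = truth["clean_absorption"][w] * power
            rel = np.abs(repaired[loss] - target[loss]) / np.maximum(target[loss], 1e-9)
            assert (rel < 0.10).mean() >= 0.95

    def test_smooth_droplet_signal_not_flattened(self):
        params = AFMIRSceneParams(seed=2, drift={}, contact_loss_rate=0.0)
        mapset, truth = synth_afmir_scene(params)
        raw = mapset.get(1742.0, "absorption")
        out = repair_contact_loss(raw)
        dm = truth["droplet_mask"]
        np.testing.assert_allclose(out[dm], raw[dm], atol=1e-9)


class TestRegistration:
    def _scene_topo(self, seed=0):
        y, x = _grid(96)
        rng = np.random.default_rng(seed)
        img = np.exp(-(((y - 40) / 8.0) ** 2 + ((x - 50) / 12.0) ** 2))
        img += 0.5 * np.exp(-(((y - 60) / 5.0) ** 2 + ((x - 30) / 6.0) ** 2))
        return img + rng.normal(0, 0.002, img.shape)

    def test_identity_on_identical_maps(self):
        img = self._scene_topo()
        t = register_maps(img, img)
        assert abs(t.dx) <= 0.05 and abs(t.dy) <= 0.05 and abs(t.theta) <= 0.05

    def test_pure_translation_recovered(self):
        img = self._scene_topo()
        mov = apply_rigid(img, RigidTransform(3.0, -2.0, 0.0), cval=0.0)
        t = register_maps(img, mov)
        assert t.dx == pytest.approx(3.0, abs=0.5)
        assert t.dy == pytest.approx(-2.0, abs=0.5)
        assert abs(t.theta) <= 0.5

    def test_translation_plus_rotation_recovered(self):
        img = self._scene_topo()
        mov = apply_rigid(img, RigidTransform(1.5, 0.0, 5.0), cval=0.0)
        t = register_maps(img, mov)
        assert t.dx == pytest.approx(1.5, abs=0.5)
        assert abs(t.dy) <= 0.5
        assert t.theta == pytest.approx(5.0, abs=0.5)

    def test_flat_image_rejected(self):
        with pytest.raises(ValueError, match="flat"):
            register_maps(np.zeros((32, 32)), np.zeros((32, 32)))

    def test_apply_then_invert_is_identity_within_interpolation(self):
        img = self._scene_topo()
        t = RigidTransform(2.0, -1.0, 4.0)
        back = apply_rigid(apply_rigid(img, t), t, inverse=True)
        ok = ~np.isnan(back)
        interior = np.zeros_like(img, dtype=bool)
        interior[8:-8, 8:-8] = True
        rms = np.sqrt(np.mean((back - img)[ok & interior] ** 2))
        assert rms < 0.05 * img.max()


class TestRescaleAndNormalize:
    def test_minimum_shifted_to_zero(self):
        a = np.array([[-2.0, 0.0], [2.0, 4.0]])
        out = rescale_topography(a)
        assert out.min() >= 0.0

    def test_uniform_map_unchanged(self):
        a = np.full((5, 5), 3.0)
        np.testing.assert_allclose(rescale_topography(a), 0.0)

    def test_ramp_percentile_floor(self):
        a = np.arange(100.0).reshape(10, 10)
        out = rescale_topography(a)
        floor = np.percentile(a, 5)  # linear-interpolation convention -> 4.95
        assert out.min() == pytest.approx(floor)
        assert (out == floor).sum() == 5  # exactly the five values below 4.95

    def test_power_normalisation(self):
        power = LaserPowerSpectrum(
            WavenumberAxis(np.arange(1500.0, 1826.0, 5.0)), np.full(66, 2.0)
        )
        a = np.ones((4, 4))
        np.testing.assert_allclose(normalize_absorption(a, 1742.0, power), 0.5)
        one = LaserPowerSpectrum(
            WavenumberAxis(np.arange(1500.0, 1826.0, 5.0)), np.ones(66)
        )
        np.testing.assert_allclose(normalize_absorption(a, 1742.0, one), a)


class TestFullChain:
    def test_artifact_free_scene_passes_through_unchanged(self):
        params = AFMIRSceneParams().zero_artifacts()
        mapset, truth = synth_afmir_scene(params)
        corrected, transforms = correct_mapset(mapset)
        for w in mapset.wavenumbers:
            assert transforms[w].is_identity(tol_px=0.05, tol_deg=0.05)
            np.testing.assert_allclose(
                corrected.get(w, "topography"), truth["clean_topography"], atol=1e-6
            )
            np.testing.assert_allclose(
                corrected.get(w, "absorption"), truth["clean_absorption"][w], atol=1e-6
            )

    def test_drift_recovered_within_half_pixel_and_half_degree(self):
        for seed in range(4):
            rng = np.random.default_rng(seed + 50)
            drift = {
                w: tuple(rng.uniform(-4, 4, 3).round(2)) for w in (1708.0, 1742.0)
            }
            params = AFMIRSceneParams(seed=seed, drift=drift)
            mapset, truth = synth_afmir_scene(params)
            _, transforms = correct_mapset(mapset)
            for w in (1708.0, 1742.0):
                t, tt = transforms[w], truth["transforms"][w]
                assert abs(t.dx - tt.dx) <= 0.5
                assert abs(t.dy - tt.dy) <= 0.5
                assert abs(t.theta - tt.theta) <= 0.5

    def test_thick_sample_refused(self):
        params = AFMIRSceneParams(thick_sample=True)
        mapset, _ = synth_afmir_scene(params)
        with pytest.raises(ThickSampleError, match="lose contact"):
            correct_mapset(mapset)


class TestSegmentationAndRatios:
    def test_hypha_mask_matches_truth(self):
        params = AFMIRSceneParams(seed=1)
        mapset, truth = synth_afmir_scene(params)
        corrected, _ = correct_mapset(mapset)
        seg = segment_afmir(corrected, seed=0)
        body = truth["body"]
        jac = (seg.foreground & body).sum() / (seg.foreground | body).sum()
        assert jac >= 0.9

    def test_seed_invariance(self):
        params = AFMIRSceneParams(seed=1)
        mapset, _ = synth_afmir_scene(params)
        corrected, _ = correct_mapset(mapset)
        m1 = segment_afmir(corrected, seed=0).foreground
        m2 = segment_afmir(corrected, seed=99).foreground
        np.testing.assert_array_equal(m1, m2)

    def test_log_ratio_arithmetic(self):
        params = AFMIRSceneParams(seed=0, drift={}).zero_artifacts()
        mapset, truth = synth_afmir_scene(params)
        corrected, _ = correct_mapset(mapset)
        seg = segment_afmir(corrected, seed=0)
        # plant known values at one foreground pixel
        r, c = np.argwhere(seg.foreground)[0]
        corrected.get(1742.0, "absorption")[r, c] = 10.0
        corrected.get(1600.0, "absorption")[r, c] = 1.0
        maps = log_ratio_maps(corrected, seg, pairs=((1742.0, 1600.0),))
        assert maps[0].values[r, c] == pytest.approx(1.0)

    def test_inverted_droplet_ratios_separate_in_sign(self):
        params = AFMIRSceneParams(form="flat_hypha", seed=3)
        mapset, truth = synth_afmir_scene(params)
        corrected, _ = correct_mapset(mapset)
        seg = segment_afmir(corrected, seed=0)
        maps = log_ratio_maps(corrected, seg, pairs=((1742.0, 1708.0),))
        vals = maps[0].values
        yy, xx = np.mgrid[0 : vals.shape[0], 0 : vals.shape[1]]
        medians = []
        for d in truth["droplets"]:
            m = (yy - d.row) ** 2 + (xx - d.col) ** 2 <= d.radius**2
            medians.append((d.tag_ffa_ratio, np.nanmedian(vals[m])))
        for ratio, med in medians:
            assert np.sign(med) == np.sign(np.log10(ratio))
            assert med == pytest.approx(np.log10(ratio), abs=0.1)

    def test_nonpositive_pixels_masked_not_clipped(self):
        params = AFMIRSceneParams(seed=0).zero_artifacts()
        mapset, _ = synth_afmir_scene(params)
        corrected, _ = correct_mapset(mapset)
        seg = segment_afmir(corrected, seed=0)
        r, c = np.argwhere(seg.foreground)[0]
        corrected.get(1742.0, "absorption")[r, c] = -1.0
        maps = log_ratio_maps(corrected, seg, pairs=((1742.0, 1600.0),))
        assert np.isnan(maps[0].values[r, c])
        assert maps[0].n_masked >= 1

    def test_laser_power_rescaling_cancels(self):
        # noise-free so the comparison is exact: noise enters before the
        # power normalisation and would not cancel
        params = AFMIRSceneParams(seed=2, noise_sd_abs=0.0)
        mapset, _ = synth_afmir_scene(params)
        corrected, _ = correct_mapset(mapset)
        seg = segment_afmir(corrected, seed=0)
        base = log_ratio_maps(corrected, seg, pairs=((1742.0, 1600.0),))[0].values

        scaled_power = LaserPowerSpectrum(
            mapset.laser_power.axis, mapset.laser_power.power * 3.0
        )
        mapset2, _ = synth_afmir_scene(params, laser_power=scaled_power)
        corrected2, _ = correct_mapset(mapset2)
        seg2 = segment_afmir(corrected2, seed=0)
        other = log_ratio_maps(corrected2, seg2, pairs=((1742.0, 1600.0),))[0].values
        ok = ~np.isnan(base) & ~np.isnan(other)
        np.testing.assert_allclose(base[ok], other[ok], atol=1e-6)


class TestPointSpectra:
    def _axis(self):
        return WavenumberAxis(np.arange(1510.0, 1801.0, 1.0))

    def test_identical_repeats_average_to_same(self):
        ax = self._axis()
        y = np.exp(-0.5 * ((ax.values - 1742.0) / 10.0) ** 2)
        g = PointSpectrumGroup("p1", [y, y, y, y], ax)
        np.testing.assert_allclose(g.average(), y)

    def test_tag_ffa_peaks_located(self):
        ax = self._axis()
        rng = np.random.default_rng(0)
        v = ax.values
        base = (
            1.0 * np.exp(-0.5 * ((v - 1742.0) / 8.0) ** 2)
            + 0.6 * np.exp(-0.5 * ((v - 1708.0) / 8.0) ** 2)
            + 0.3 * np.exp(-0.5 * ((v - 1600.0) / 12.0) ** 2)
        )
        groups = [
            PointSpectrumGroup(
                f"p{i}", [base * (1 + 0.1 * i) + rng.normal(0, 0.01, len(ax)) for _ in range(4)], ax
            )
            for i in range(3)
        ]
        out = preprocess_point_spectra(groups)
        from mycoftir.instrument_compare import pick_peaks
        from mycoftir.preprocess import SpectralRegion

        pl = pick_peaks(out.mean_spectrum(), SpectralRegion([(1510.0, 1800.0)]))
        for target in (1742.0, 1708.0):
            assert np.min(np.abs(pl.positions - target)) <= 2.0

    def test_shoulder_resolved_in_second_derivative(self):
        ax = self._axis()
        v = ax.values
        base = 1.0 * np.exp(-0.5 * ((v - 1742.0) / 6.0) ** 2) + 0.5 * np.exp(
            -0.5 * ((v - 1725.0) / 6.0) ** 2
        )
        groups = [PointSpectrumGroup("p0", [base] * 4, ax)]
        out = preprocess_point_spectra(groups, second_derivative=True)
        d2 = out.matrix[0]
        from scipy.signal import find_peaks

        idx, _ = find_peaks(-d2, prominence=0.01 * (-d2).max())
        mins = v[idx]
        assert np.min(np.abs(mins - 1742.0)) <= 2.0
        assert np.min(np.abs(mins - 1725.0)) <= 3.0

    def test_mismatched_repeat_axes_rejected(self):
        ax = self._axis()
        with pytest.raises(ValueError):
            PointSpectrumGroup("p", [np.zeros(10)], ax)
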