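import numpy as np
import pytest

from neuroqc.errors import ValidationError
from neuroqc.fmri_metrics import (
    RigidParams,
    compute_dvars,
    compute_sfnr,
    estimate_motion,
    framewise_displacement,
    functional_report,
    outlier_fraction,
    per_frame_descriptors,
    spectrum_stats,
    temporal_snr,
    velocity,
)
from neuroqc.synthetic_phantoms import MotionEvent, PhantomSpec, make_functional
from neuroqc.volume_io import Series4D

from conftest import MOTION_GEOMETRY


def _static_series(rng, shape=(16, 16, 16), n=20, mu=1000.0, sigma=0.0, tr=2.0):
    data = np.full(shape + (n,), mu)
    if sigma:
        data = data + rng.normal(0, sigma, size=data.shape)
    return Series4D(data, (1.0, 1.0, 1.0), frame_interval=tr)


def _params(translations, rotations=None):
    t = np.asarray(translations, dtype=float)
    r = np.zeros_like(t) if rotations is None else np.asarray(rotations, dtype=float)
    return RigidParams(t, r, np.zeros(t.shape[0], bool))


class TestFramewiseDisplacement:
    def test_static_zero(self):
        fd, max_fd, count = framewise_displacement(_params(np.zeros((10, 3))))
        np.testing.assert_array_equal(fd, 0.0)
        assert count == 0

    def test_single_translation_jump(self):
        t = np.zeros((8, 3))
        t[5:, 0] = 0.6  # jump between frames 4 and 5
        fd, max_fd, count = framewise_displacement(_params(t))
        assert fd[5] == pytest.approx(0.6)
        assert max_fd == pytest.approx(0.6)
        assert count == 1

    def test_rotation_arc_length(self):
        r = np.zeros((3, 3))
        r[1:, 2] = 0.01  # 0.01 rad about z
        fd, _, _ = framewise_displacement(_params(np.zeros((3, 3)), r), head_radius=50.0)
        assert fd[1] == pytest.approx(0.5)
        assert fd[2] == 0.0

    def test_offset_invariance(self, rng):
        t = rng.normal(size=(10, 3))
        r = rng.normal(scale=0.01, size=(10, 3))
        fd1, _, _ = framewise_displacement(_params(t, r))
        fd2, _, _ = framewise_displacement(_params(t + 1.23, r + 0.045))
        np.testing.assert_allclose(fd1, fd2, atol=1e-12)

    def test_to_first_mode(self):
        t = np.zeros((4, 3))
        t[1:, 0] = 1.0
        fd, _, _ = framewise_displacement(_params(t), mode="to-first")
        np.testing.assert_allclose(fd, [0.0, 1.0, 1.0, 1.0])

    def test_missing_frame_flagged(self):
        p = _params(np.zeros((5, 3)))
        p.missing[2] = True
        fd, _, _ = framewise_displacement(p)
        assert np.isnan(fd[2]) and np.isnan(fd[3])


class TestDVARS:
    def test_constant_series_zero(self, rng):
        series = _static_series(rng)
        mask = np.ones((16, 16, 16), bool)
        dvars, dmax, dmin, count = compute_dvars(series, mask)
        np.testing.assert_array_equal(dvars, 0.0)
        assert count == 0

    def test_one_voxel_step_hand_value(self):
        data = np.full((8, 8, 8, 2), 1000.0)
        mask = np.zeros((8, 8, 8), bool)
        mask[4, 4, 4] = True
        data[4, 4, 4, 1] = 1060.0
        series = Series4D(data, (1.0, 1.0, 1.0))
        dvars, dmax, _, count = compute_dvars(series, mask, normalize=None, threshold=50.0)
        assert dvars[1] == pytest.approx(60.0)
        assert count == 1

    def test_scaling_invariance_with_normalisation(self, rng):
        data = rng.normal(1000.0, 20.0, size=(12, 12, 12, 10))
        mask = np.ones((12, 12, 12), bool)
        d1, *_ = compute_dvars(Series4D(data, (1.0, 1.0, 1.0)), mask)
        d2, *_ = compute_dvars(Series4D(data * 2.0, (1.0, 1.0, 1.0)), mask)
        np.testing.assert_allclose(d1[1:], d2[1:], rtol=1e-9)

    def test_max_ge_min(self, rng):
        data = rng.normal(1000.0, 20.0, size=(12, 12, 12, 10))
        _, dmax, dmin, _ = compute_dvars(Series4D(data, (1.0, 1.0, 1.0)),
                                         np.ones((12, 12, 12), bool))
        assert dmax >= dmin

    def test_empty_mask_rejected(self, rng):
        series = _static_series(rng)
        with pytest.raises(ValidationError):
            compute_dvars(series, np.zeros((16, 16, 16), bool))


class TestTemporalSNR:
    def test_sampling_distribution(self, rng):
        data = rng.normal(200.0, 10.0, size=(12, 12, 12, 200))
        series = Series4D(data, (1.0, 1.0, 1.0), frame_interval=2.0)
        _, avg, n_excl = temporal_snr(series, np.ones((12, 12, 12), bool))
        assert avg == pytest.approx(20.0, abs=2.0)
        assert n_excl == 0

    def test_constant_series_flagged(self, rng):
        series = _static_series(rng)
        _, avg, n_excl = temporal_snr(series, np.ones((16, 16, 16), bool))
        assert avg is None
        assert n_excl == 16**3

    def test_halving_sigma_doubles_tsnr(self, rng):
        avgs = []
        for sigma in (20.0, 10.0, 5.0):
            data = rng.normal(200.0, sigma, size=(10, 10, 10, 150))
            series = Series4D(data, (1.0, 1.0, 1.0))
            _, avg, _ = temporal_snr(series, np.ones((10, 10, 10), bool))
            avgs.append(avg)
        assert avgs[1] / avgs[0] == pytest.approx(2.0, rel=0.1)
        assert avgs[2] / avgs[1] == pytest.approx(2.0, rel=0.1)


class TestSFNR:
    def test_pure_quadratic_drift_flagged(self):
        n = 50
        x = np.linspace(-1, 1, n)
        drift = 5.0 * x**2 + 3.0 * x + 100.0
        data = np.broadcast_to(drift, (8, 8, 8, n)).copy()
        series = Series4D(data, (1.0, 1.0, 1.0))
        _, median, n_excl = compute_sfnr(series, np.ones((8, 8, 8), bool))
        assert median is None
        assert n_excl == 8**3

    def test_drift_plus_noise(self, rng):
        n = 200
        x = np.linspace(-1, 1, n)
        drift = 30.0 * x**2 - 10.0 * x
        data = 200.0 + drift + rng.normal(0, 10.0, size=(8, 8, 8, n))
        series = Series4D(data, (1.0, 1.0, 1.0))
        _, median, _ = compute_sfnr(series, np.ones((8, 8, 8), bool))
        assert median == pytest.approx(20.0, rel=0.1)

    def test_equals_tsnr_without_trend(self, rng):
        data = rng.normal(300.0, 15.0, size=(10, 10, 10, 200))
        series = Series4D(data, (1.0, 1.0, 1.0))
        mask = np.ones((10, 10, 10), bool)
        _, avg_tsnr, _ = temporal_snr(series, mask)
        _, median_sfnr, _ = compute_sfnr(series, mask)
        assert median_sfnr == pytest.approx(avg_tsnr, rel=0.02)


class TestOutlierFraction:
    def test_gaussian_calibration(self, rng):
        data = rng.normal(100.0, 5.0, size=(14, 14, 14, 60))
        series = Series4D(data, (1.0, 1.0, 1.0))
        frac = outlier_fraction(series, np.ones((14, 14, 14), bool))
        assert 0.0005 <= frac.mean() <= 0.002  # alpha = 0.001 within factor 2

    def test_spike_injection(self, rng):
        data = rng.normal(100.0, 5.0, size=(14, 14, 14, 60))
        mask = np.ones((14, 14, 14), bool)
        idx = np.argwhere(mask)
        chosen = idx[rng.choice(idx.shape[0], size=int(0.05 * idx.shape[0]), replace=False)]
        data[tuple(chosen.T) + (30,)] += 50.0  # 10 sigma
        series = Series4D(data, (1.0, 1.0, 1.0))
        frac = outlier_fraction(series, mask)
        assert frac[30] == pytest.approx(0.05, abs=0.01)

    def test_constant_series_zero(self, rng):
        series = _static_series(rng)
        frac = outlier_fraction(series, np.ones((16, 16, 16), bool))
        np.testing.assert_array_equal(frac, 0.0)


class TestVelocity:
    def test_constant_zero(self, rng):
        np.testing.assert_array_equal(velocity(_static_series(rng)), 0.0)

    def test_global_step(self, rng):
        data = np.full((8, 8, 8, 6), 100.0)
        data[..., 3:] += 5.0
        v = velocity(Series4D(data, (1.0, 1.0, 1.0)))
        np.testing.assert_allclose(v, [0, 0, 0, 5.0, 0, 0])

    def test_brute_force(self, rng):
        data = rng.normal(size=(8, 8, 8, 7))
        v = velocity(Series4D(data, (1.0, 1.0, 1.0)))
        means = data.mean(axis=(0, 1, 2))
        np.testing.assert_allclose(v[1:], np.diff(means), atol=1e-12)


class TestSpectrum:
    def test_sinusoid_peak_at_frequency(self):
        n, tr, f0 = 200, 2.0, 0.1
        t = np.arange(n) * tr
        signal = 100.0 + 10.0 * np.sin(2 * np.pi * f0 * t)
        data = np.broadcast_to(signal, (8, 8, 8, n)).copy()
        series = Series4D(data, (1.0, 1.0, 1.0), frame_interval=tr)
        freqs, mags, _, smax = spectrum_stats(series, np.ones((8, 8, 8), bool))
        assert freqs[np.argmax(mags)] == pytest.approx(f0)

    def test_constant_series_zero_spectrum(self, rng):
        _, mags, smean, smax = spectrum_stats(_static_series(rng),
                                              np.ones((16, 16, 16), bool))
        assert smax == pytest.approx(0.0, abs=1e-9)

    def test_white_noise_flat(self, rng):
        n = 4096
        data = rng.normal(0, 1.0, size=(8, 8, 8, n))
        series = Series4D(data, (1.0, 1.0, 1.0), frame_interval=1.0)
        _, mags, smean, _ = spectrum_stats(series, np.ones((8, 8, 8), bool))
        # bin-averaged magnitudes flat within 3 SE across 4 coarse bands
        bands = np.array_split(mags, 4)
        band_means = [b.mean() for b in bands]
        se = mags.std() / np.sqrt(len(bands[0]))
        assert max(band_means) - min(band_means) < 6 * se

    def test_missing_tr_warns(self, rng):
        data = rng.normal(size=(8, 8, 8, 16))
        series = Series4D(data, (1.0, 1.0, 1.0), frame_interval=None)
        with pytest.warns(UserWarning, match="cycles/frame"):
            spectrum_stats(series, np.ones((8, 8, 8), bool))


@pytest.mark.slow
class TestMotionEstimation:
    def test_identity_recovery(self, rng):
        spec = PhantomSpec(n_frames=3, noise_sigma=0.0, **MOTION_GEOMETRY)
        series, truth = make_functional(spec)
        params = estimate_motion(series, truth["brain_mask"])
        assert np.abs(params.translations).max() < 0.01
        assert np.rad2deg(np.abs(params.rotations)).max() < 0.01

    def test_translation_recovery(self):
        spec = PhantomSpec(n_frames=4, motion_events=(
            MotionEvent(frame=3, translation_mm=(1.0, -0.5, 0.25)),), **MOTION_GEOMETRY)
        series, truth = make_functional(spec)
        params = estimate_motion(series, truth["brain_mask"])
        assert np.abs(params.translations - truth["translations"]).max() < 0.1

    def test_rotation_recovery(self):
        spec = PhantomSpec(n_frames=2, motion_events=(
            MotionEvent(frame=1, rotation_deg=(0.0, 0.0, 2.0)),), **MOTION_GEOMETRY)
        series, truth = make_functional(spec)
        params = estimate_motion(series, truth["brain_mask"])
        assert np.rad2deg(np.abs(params.rotations - truth["rotations"])).max() < 0.2


class TestPerFrameDescriptors:
    def test_static_series_flat(self, rng):
        series = _static_series(rng, n=4)
        mask = np.zeros((16, 16, 16), bool)
        mask[4:12, 4:12, 4:12] = True
        msi, com, fwhm, slice_var = per_frame_descriptors(series, mask,
                                                          fwhm_min_voxels=100)
        np.testing.assert_allclose(np.diff(com, axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(slice_var, 0.0, atol=1e-12)

    def test_matches_direct_calls(self, rng):
        from scipy import ndimage

        data = rng.normal(100, 5, size=(16, 16, 16, 4))
        series = Series4D(data, (1.0, 1.0, 1.0))
        mask = np.zeros((16, 16, 16), bool)
        mask[4:12, 4:12, 4:12] = True
        msi, com, _, _ = per_frame_descriptors(series, mask, fwhm_min_voxels=100)
        for t in range(4):
            assert msi[t] == data[..., t].mean()
            expected = np.asarray(ndimage.center_of_mass(data[..., t])) - 7.5
            np.testing.assert_allclose(com[t], expected, atol=1e-12)

    def test_injected_shift_spikes_com(self):
        blob = np.zeros((16, 16, 16))
        blob[4:12, 4:12, 4:12] = 100.0
        frames = [blob, blob, blob, np.roll(blob, 2, axis=0), blob]
        series = Series4D(np.stack(frames, axis=-1), (1.0, 1.0, 1.0))
        _, com, _, _ = per_frame_descriptors(series, blob > 0, fwhm_min_voxels=100)
        assert com[3, 0] == pytest.approx(2.0)
        np.testing.assert_allclose(com[[0, 1, 2, 4], 0], 0.0, atol=1e-12)


@pytest.mark.slow
class TestFunctionalReport:
    def test_injected_events_counted(self):
        events = tuple(MotionEvent(frame=f, translation_mm=(t, 0, 0))
                       for f, t in ((3, 1.0), (6, 0.0), (9, 2.0)))
        spec = PhantomSpec(n_frames=12, motion_events=events, **MOTION_GEOMETRY)
        series, truth = make_functional(spec)
        report = functional_report(
            series, external_brain_mask=truth["brain_mask"],
            motion_params=RigidParams(truth["translations"], truth["rotations"],
                                      np.zeros(12, bool)))
        assert report.n_fd_gt == 3  # jumps of 1.0, 1.0, 2.0 mm
        scalars = report.scalar_dict()
        assert set(scalars) == {"max_fd", "n_fd_gt", "avg_tsnr",
                                "max_dvars", "min_dvars", "n_dvars_gt"}

    def test_clean_series_counts_zero(self):
        spec = PhantomSpec(n_frames=6, noise_sigma=1.0, **MOTION_GEOMETRY)
        series, truth = make_functional(spec)
        report = functional_report(series, external_brain_mask=truth["brain_mask"],
                                   run_motion=False,
                                   motion_params=RigidParams(
                                       truth["translations"], truth["rotations"],
                                       np.zeros(6, bool)))
        assert report.n_fd_gt == 0
        assert report.n_dvars_gt == 0
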