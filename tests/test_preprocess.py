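"""Smoothing, bandpass and percent-signal-change behavior."""

import numpy as np
import pytest

from trialfc import (Band, BoldRun, bandpass, gaussian_smooth,
                     make_brain_mask, percent_signal_change, preprocess_run)


def run_from(data, voxel=3.5, tr=2.5):
    return BoldRun(data=data, voxel_size=(voxel,) * 3, tr=tr)


@pytest.fixture
def noise_run():
    rng = np.random.default_rng(0)
    return run_from(100 + rng.standard_normal((8, 8, 6, 48)))


class TestSmoothing:
    def test_fwhm_zero_is_identity(self, noise_run):
        out = gaussian_smooth(noise_run, 0.0)
        np.testing.assert_array_equal(out.data, noise_run.data)

    def test_negative_fwhm_rejected(self, noise_run):
        with pytest.raises(ValueError):
            gaussian_smooth(noise_run, -1.0)

    def test_impulse_response_width_matches_fwhm(self):
        data = np.zeros((15, 15, 15, 4))
        data[7, 7, 7, :] = 1.0
        run = run_from(data, voxel=3.5)
        out = gaussian_smooth(run, 4.0).data[:, 7, 7, 0]
        half = out.max() / 2
        above = np.where(out >= half)[0]
        # linear interpolation of the crossing points, in mm
        lo, hi = above[0], above[-1]
        x_lo = lo - (out[lo] - half) / (out[lo] - out[lo - 1])
        x_hi = hi + (out[hi] - half) / (out[hi] - out[hi + 1])
        measured = (x_hi - x_lo) * 3.5
        assert measured == pytest.approx(4.0, abs=3.5)  # within one voxel

    def test_constant_volume_unchanged(self):
        run = run_from(np.full((10, 10, 8, 4), 7.0))
        out = gaussian_smooth(run, 4.0)
        np.testing.assert_allclose(out.data, 7.0, rtol=1e-12)


class TestBandpass:
    BAND = Band(0.009, 0.08)

    def test_dc_series_removed(self):
        x = np.full(288, 5.0)
        np.testing.assert_allclose(bandpass(x, 2.5, self.BAND), 0, atol=1e-12)

    def test_inband_bin_passes_unchanged(self):
        # 29 cycles over 720 s = 0.0403 Hz, an exact rfft bin inside the band
        t = np.arange(288) * 2.5
        x = 3.0 + np.sin(2 * np.pi * (29 / 720.0) * t)
        out = bandpass(x, 2.5, self.BAND)
        np.testing.assert_allclose(out, x - x.mean(), atol=1e-10)

    def test_out_of_band_sinusoid_suppressed(self):
        t = np.arange(288) * 2.5
        x = np.sin(2 * np.pi * 0.15 * t)
        assert np.abs(bandpass(x, 2.5, self.BAND)).max() < 1e-10

    def test_matches_explicit_dft_oracle(self):
        # brute-force DFT matrix projection on a short series
        rng = np.random.default_rng(1)
        n, tr = 32, 2.5
        x = rng.standard_normal(n)
        freqs = np.fft.fftfreq(n, d=tr)
        keep = (np.abs(freqs) >= self.BAND.low) & \
               (np.abs(freqs) <= self.BAND.high)
        w = np.exp(-2j * np.pi * np.outer(np.arange(n), np.arange(n)) / n)
        spec = w @ x
        spec[~keep] = 0
        expect = (w.conj().T @ spec).real / n
        np.testing.assert_allclose(bandpass(x, tr, self.BAND), expect,
                                   atol=1e-10)

    def test_idempotent_and_linear(self):
        rng = np.random.default_rng(2)
        x, y = rng.standard_normal((2, 144))
        bp = lambda v: bandpass(v, 2.5, self.BAND)
        np.testing.assert_allclose(bp(bp(x)), bp(x), atol=1e-12)
        np.testing.assert_allclose(bp(2.0 * x - 3.0 * y),
                                   2.0 * bp(x) - 3.0 * bp(y), atol=1e-12)

    def test_band_at_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(np.zeros(48), 2.5, Band(0.009, 0.25))

    def test_commutes_with_spatial_smoothing(self, noise_run):
        a = gaussian_smooth(noise_run, 4.0)
        a = a.with_data(bandpass(a.data, a.tr, self.BAND), "bp")
        b = noise_run.with_data(
            bandpass(noise_run.data, noise_run.tr, self.BAND), "bp")
        b = gaussian_smooth(b, 4.0)
        np.testing.assert_allclose(a.data, b.data, atol=1e-9)


class TestPercentSignalChange:
    def test_definitional_scaling(self):
        run = run_from(np.full((2, 2, 2, 4), 2.0))
        out = percent_signal_change(run, np.full((2, 2, 2), 100.0))
        np.testing.assert_allclose(out.data, 2.0)

    def test_doubling_baseline_halves_series(self, noise_run):
        base = noise_run.data.mean(axis=3)
        a = percent_signal_change(noise_run, base)
        b = percent_signal_change(noise_run, 2 * base)
        np.testing.assert_allclose(a.data, 2 * b.data, rtol=1e-12)

    def test_correlation_invariant_under_psc(self, noise_run):
        # Pearson r is invariant to positive per-voxel scaling, so maps
        # from PSC and raw bandpassed data agree voxel by voxel
        band = Band(0.009, 0.08)
        bp = noise_run.with_data(
            bandpass(noise_run.data, noise_run.tr, band), "bp")
        psc = percent_signal_change(bp, noise_run.data.mean(axis=3))
        template = np.sin(np.linspace(0, 3, 48))

        def corr(run):
            x = run.data.reshape(-1, 48)
            xc = x - x.mean(1, keepdims=True)
            tc = template - template.mean()
            return (xc @ tc) / np.sqrt((xc**2).sum(1) * (tc**2).sum())

        np.testing.assert_allclose(corr(psc), corr(bp), atol=1e-12)


class TestBrainMask:
    def test_uniform_volume_fully_included(self):
        mask = make_brain_mask(np.ones((6, 6, 6)), fraction=0.5)
        assert mask.n_voxels == 216

    def test_larger_blob_wins(self):
        vol = np.zeros((20, 10, 10))
        vol[1:7, 2:8, 2:8] = 1.0    # 216 voxels
        vol[12:15, 2:5, 2:5] = 1.0  # 27 voxels
        mask = make_brain_mask(vol, fraction=0.5)
        assert mask.n_voxels == 216
        assert not mask.inside[12:15].any()

    def test_ellipsoid_phantom_count_within_2pct(self):
        shape = (24, 24, 18)
        center = [(n - 1) / 2 for n in shape]
        semi = [0.4 * n for n in shape]
        coords = np.indices(shape).astype(float)
        d2 = sum(((coords[i] - center[i]) / semi[i]) ** 2 for i in range(3))
        truth = d2 <= 1.0
        vol = np.where(truth, 1000.0, 10.0)
        mask = make_brain_mask(vol, fraction=0.3)
        assert mask.n_voxels == pytest.approx(truth.sum(), rel=0.02)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            make_brain_mask(np.zeros((4, 4, 4)), fraction=0.5)


def test_full_chain_deterministic(noise_run):
    a, mask_a = preprocess_run(noise_run)
    b, mask_b = preprocess_run(noise_run)
    np.testing.assert_array_equal(a.data, b.data)
    np.testing.assert_array_equal(mask_a.inside, mask_b.inside)
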