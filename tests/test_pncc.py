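"""Stage-by-stage oracles and end-to-end invariants of the PNCC chain."""

import numpy as np
import pytest

from pcgpah.pncc import (
    PnccConfig,
    adaptive_frame_geometry,
    adaptive_stft,
    asymmetric_noise_suppression,
    filterbank_power,
    gammatone_filterbank,
    medium_time_power,
    pncc_image,
    power_normalize_and_compress,
    pre_emphasis,
    spectral_weight_smoothing,
)

RATE = 2500


class TestPreEmphasis:
    def test_examples(self):
        np.testing.assert_allclose(
            pre_emphasis(np.array([1.0, 1.0, 1.0])), [1.0, 0.05, 0.05]
        )
        np.testing.assert_allclose(
            pre_emphasis(np.array([1.0, 0.0, 0.0])), [1.0, -0.95, 0.0]
        )

    def test_suppresses_dc(self):
        rng = np.random.default_rng(0)
        x = 5.0 + 0.1 * rng.normal(size=2000)
        y = pre_emphasis(x)
        assert np.mean(np.abs(y[1:])) < 0.1 * np.mean(np.abs(x))


class TestAdaptiveStft:
    @pytest.mark.parametrize("n", [1500, 2400, 2047])
    def test_fixed_frame_count(self, n):
        rng = np.random.default_rng(1)
        spectra = adaptive_stft(rng.normal(size=n), 64)
        assert spectra.shape[0] == 64

    def test_single_frame_covers_cycle(self):
        x = np.arange(1000, dtype=float)
        frame_len, hop = adaptive_frame_geometry(x.size, 1)
        assert frame_len == 1000

    def test_constant_tone_peak_stable_across_lengths(self):
        for n in (1500, 2400):
            t = np.arange(n) / RATE
            spectra = adaptive_stft(np.sin(2 * np.pi * 200 * t), 32)
            frame_len, _ = adaptive_frame_geometry(n, 32)
            freqs = np.fft.rfftfreq(frame_len, 1 / RATE)
            bin_hz = freqs[1]
            for m in (5, 15, 25):
                peak = freqs[np.argmax(np.abs(spectra[m]))]
                assert abs(peak - 200.0) <= 1.5 * bin_hz

    def test_too_short_cycle_fails(self):
        with pytest.raises(ValueError):
            adaptive_stft(np.ones(10), 64)


class TestFilterbank:
    def test_normalization_exact(self):
        fb = gammatone_filterbank(40, 512, RATE)
        np.testing.assert_allclose(fb.sum(axis=1), 1.0, atol=1e-9)

    def test_white_spectrum_gives_unit_power(self):
        fb = gammatone_filterbank(40, 512, RATE)
        spectra = np.ones((3, 257), dtype=complex)
        p = filterbank_power(spectra, fb)
        np.testing.assert_allclose(p, 1.0, atol=1e-9)

    def test_tone_activates_matching_channel(self):
        fb = gammatone_filterbank(40, 512, RATE)
        freqs = np.fft.rfftfreq(512, 1 / RATE)
        centers = [float(freqs[np.argmax(row)]) for row in fb]
        for target_channel in (5, 20, 35):
            spectrum = np.zeros((1, 257), dtype=complex)
            k = int(np.argmin(np.abs(freqs - centers[target_channel])))
            spectrum[0, k] = 1.0
            p = filterbank_power(spectrum, fb)
            assert int(np.argmax(p[0])) == target_channel


class TestMediumTimePower:
    def test_constant_invariant(self):
        p = np.full((20, 8), 3.3)
        np.testing.assert_allclose(medium_time_power(p), 3.3)

    def test_interior_impulse_spreads_one_fifth(self):
        p = np.zeros((21, 4))
        p[10, 2] = 1.0
        q = medium_time_power(p, 2)
        assert q[10, 2] == pytest.approx(0.2)
        assert q[8, 2] == pytest.approx(0.2)
        assert q[7, 2] == 0.0

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=(30, 10))
        q = medium_time_power(p, 2)
        for m in range(30):
            lo, hi = max(0, m - 2), min(30, m + 3)
            expect = p[lo:hi].mean(axis=0)
            np.testing.assert_allclose(q[m], expect, rtol=1e-12)


class TestNoiseSuppression:
    def test_zero_stays_zero(self):
        assert np.all(asymmetric_noise_suppression(np.zeros((30, 6))) == 0)

    def test_constant_input_residual_bounded(self):
        q = np.full((200, 4), 2.0)
        r = asymmetric_noise_suppression(q)
        assert np.all(r >= 0) and np.all(r <= 2.0 + 1e-12)

    def test_pedestal_attenuated_bursts_preserved(self):
        config = PnccConfig(asym_lambda_a=0.95)
        n = 600
        q = np.full((n, 2), 1.0)
        burst_frames = [400, 450, 500]
        for m in burst_frames:
            q[m] += 50.0
        r = asymmetric_noise_suppression(q, config)
        steady = r[380:395, 0].mean()
        assert steady < 0.1  # >= 10 dB below the unit pedestal
        for m in burst_frames:
            assert r[m, 0] > 25.0  # burst survives


class TestSpectralSmoothing:
    def test_identity_transfer(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0.5, 1.5, (10, 12))
        q = rng.uniform(0.5, 1.5, (10, 12))
        t = spectral_weight_smoothing(q, q, p)
        np.testing.assert_allclose(t, p, rtol=1e-12)

    def test_zero_ratio_zeroes_output(self):
        p = np.ones((5, 8))
        q = np.ones((5, 8))
        assert np.all(spectral_weight_smoothing(np.zeros((5, 8)), q, p) == 0)

    def test_matches_bruteforce_double_loop(self):
        rng = np.random.default_rng(4)
        shape = (12, 10)
        r = rng.uniform(0.1, 1.0, shape)
        q = rng.uniform(0.5, 2.0, shape)
        p = rng.uniform(0.1, 3.0, shape)
        n_nb = 4
        t = spectral_weight_smoothing(r, q, p, n_nb)
        for m in range(shape[0]):
            for l in range(shape[1]):
                lo, hi = max(0, l - n_nb), min(shape[1], l + n_nb + 1)
                s = np.mean([r[m, lp] / q[m, lp] for lp in range(lo, hi)])
                assert t[m, l] == pytest.approx(p[m, l] * s, rel=1e-12)


class TestNormalization:
    def test_unit_ratio_maps_to_one(self):
        t = np.full((40, 8), 2.5)
        v = power_normalize_and_compress(t, mu_forget=0.5)
        np.testing.assert_allclose(v, 1.0, atol=1e-12)

    def test_matches_bruteforce_recursion(self):
        rng = np.random.default_rng(5)
        t = rng.uniform(0.1, 2.0, (25, 6))
        lam = 0.9
        v = power_normalize_and_compress(t, lam, scale_k=1.3)
        mu_prev = t[0].mean()
        for m in range(25):
            mu_prev = lam * mu_prev + (1 - lam) * t[m].mean()
            expect = (1.3 * t[m] / mu_prev) ** (1 / 15)
            np.testing.assert_allclose(v[m], expect, rtol=1e-9)


class TestImage:
    def test_shape_contract_across_cycle_lengths(self, true_cycles):
        for cyc in true_cycles[:4]:
            img = pncc_image(cyc)
            assert img.values.shape == (64, 40)
            assert np.isfinite(img.values).all()
            assert np.all(img.values >= 0)

    def test_amplitude_invariance(self, true_cycles):
        for cyc in true_cycles[:5]:
            ref = pncc_image(cyc).values
            for c in (0.1, 10.0):
                scaled = pncc_image(c * cyc).values
                assert np.max(np.abs(scaled - ref)) < 1e-6
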