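"""Power-normalized feature images of cardiac cycles.

The chain converts one cardiac cycle into a fixed-size non-negative
image for the CNN feature extractor:

1. pre-emphasis ``y[n] = x[n] - 0.95 x[n-1]``;
2. an adaptive STFT whose frame length scales with the cycle so every
   cycle yields exactly ``n_frames_out`` Hamming-windowed frames;
3. a gammatone-weighted filterbank power (each channel's squared
   frequency response sums to 1 on the DFT grid);
4. medium-time power: a running mean over +/-M frames (M = 2);
5. asymmetric noise suppression: a fast-rise/slow-fall first-order
   tracker estimates the noise floor per channel; the floor is
   subtracted, half-wave rectified, and trailing energy is limited by
   temporal masking;
6. spectral weight smoothing: the noise-suppression transfer ratio is
   averaged over neighbouring channels and applied to the raw power;
7. mean-power normalization with a running average (forgetting factor
   lambda_mu) followed by a 1/15 power-law compression.

Stages 4-7 operate on power, so the image is invariant to the
recording gain; stage 7's power law mimics auditory rate-level
compression. The resulting matrix (frames x channels) is used directly
as the image — no DCT is taken, so the full spectro-temporal layout is
preserved for the CNN; an optional DCT export yields conventional
cepstral coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy.fft import dct
from scipy.signal.windows import hamming

from .audio_io import WORKING_RATE


@dataclass
class PnccConfig:
    """Tunable constants of the power-normalization chain.

    Defaults follow the published constants of the power-normalized
    cepstral feature lineage, with the filterbank capped at 1 kHz
    because heart sounds carry no diagnostic content above it.
    """

    preemph_k: float = 0.95
    n_frames_out: int = 64
    n_channels: int = 40
    fmin_hz: float = 25.0
    fmax_hz: float = 1000.0
    smoothing_frames: int = 2  # M: +/- frames of the medium-time mean
    freq_smooth_n: int = 4  # N: +/- channels of the spectral smoothing
    mu_forget: float = 0.999  # lambda_mu of the mean-power tracker
    power_exponent: float = 1.0 / 15.0
    asym_lambda_a: float = 0.999  # slow branch of the noise-floor tracker
    asym_lambda_b: float = 0.5  # fast branch
    masking_lambda: float = 0.85  # temporal-masking decay
    masking_mu: float = 0.2  # masked-frame attenuation
    excitation_c: float = 2.0  # excitation test: Q >= c * floor
    scale_k: float = 1.0  # arbitrary normalization constant


@dataclass
class PnccImage:
    """Fixed-shape (n_frames_out x n_channels) non-negative feature image."""

    values: np.ndarray
    cycle_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("PnccImage must be a 2-D matrix")


def pre_emphasis(x: np.ndarray, k: float = 0.95) -> np.ndarray:
    """High-pass pre-emphasis: y[0] = x[0], y[n] = x[n] - k x[n-1]."""
    x = np.asarray(x, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty waveform")
    y = x.copy()
    y[1:] -= k * x[:-1]
    return y


def adaptive_frame_geometry(n_samples: int, n_frames_out: int) -> Tuple[int, int]:
    """Frame length and hop tiling a cycle into exactly ``n_frames_out`` frames.

    Hop is chosen as floor(n / (F + 1)) with 50% overlap
    (frame = 2 * hop), so (F - 1) * hop + frame <= n for any length.
    """
    if n_samples < n_frames_out + 1:
        raise ValueError(
            f"cycle of {n_samples} samples cannot tile {n_frames_out} frames"
        )
    hop = n_samples // (n_frames_out + 1)
    return 2 * hop, hop


def adaptive_stft(x: np.ndarray, n_frames_out: int) -> np.ndarray:
    """Hamming-windowed STFT with cycle-dependent frame length.

    Returns complex spectra of shape (n_frames_out, frame_len // 2 + 1).
    """
    x = np.asarray(x, dtype=np.float64)
    frame_len, hop = adaptive_frame_geometry(x.size, n_frames_out)
    window = hamming(frame_len, sym=False)
    frames = np.stack(
        [x[m * hop : m * hop + frame_len] for m in range(n_frames_out)]
    )
    return np.fft.rfft(frames * window, axis=1)


def _erb(f: np.ndarray) -> np.ndarray:
    return 24.7 * (4.37 * f / 1000.0 + 1.0)


def _hz_to_erb_rate(f: np.ndarray) -> np.ndarray:
    return 21.4 * np.log10(1.0 + 0.00437 * f)


def _erb_rate_to_hz(e: np.ndarray) -> np.ndarray:
    return (10.0 ** (e / 21.4) - 1.0) / 0.00437


def gammatone_filterbank(
    n_channels: int,
    n_fft: int,
    rate: float,
    fmin: float = 25.0,
    fmax: float = 1000.0,
) -> np.ndarray:
    """Squared-magnitude gammatone weights on the rFFT grid.

    Channel centers are spaced on the ERB-rate scale between ``fmin``
    and ``fmax``; each row is renormalized so its squared response sums
    exactly to 1 (the filterbank normalization the power stage assumes).
    Returns shape (n_channels, n_fft // 2 + 1).
    """
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / rate)
    centers = _erb_rate_to_hz(
        np.linspace(_hz_to_erb_rate(np.array(fmin)), _hz_to_erb_rate(np.array(fmax)), n_channels)
    )
    bw = 1.019 * _erb(centers)
    # 4th-order gammatone magnitude response
    h = (1.0 + ((freqs[None, :] - centers[:, None]) / bw[:, None]) ** 2) ** -2.0
    h2 = h**2
    return h2 / h2.sum(axis=1, keepdims=True)


def filterbank_power(spectra: np.ndarray, filterbank: np.ndarray) -> np.ndarray:
    """Short-time spectral power per frame and channel: P[m, l]."""
    return np.abs(spectra) ** 2 @ filterbank.T


def medium_time_power(p: np.ndarray, m_frames: int = 2) -> np.ndarray:
    """Running mean of P over +/-``m_frames``; edge windows shrink."""
    n = p.shape[0]
    q = np.empty_like(p)
    for m in range(n):
        lo = max(0, m - m_frames)
        hi = min(n, m + m_frames + 1)
        q[m] = p[lo:hi].mean(axis=0)
    return q


def _asymmetric_lowpass(q: np.ndarray, lam_a: float, lam_b: float) -> np.ndarray:
    """First-order tracker: slow (lam_a) when rising, fast (lam_b) when falling.

    Rising inputs are followed sluggishly so transients do not drag the
    floor up; falling inputs are followed quickly so the floor hugs the
    noise pedestal.
    """
    out = np.empty_like(q)
    prev = 0.9 * q[0]
    for m in range(q.shape[0]):
        rise = q[m] >= prev
        nxt = np.where(
            rise,
            lam_a * prev + (1 - lam_a) * q[m],
            lam_b * prev + (1 - lam_b) * q[m],
        )
        out[m] = nxt
        prev = nxt
    return out


def asymmetric_noise_suppression(
    q: np.ndarray, config: Optional[PnccConfig] = None
) -> np.ndarray:
    """Noise-floor subtraction with half-wave rectification and masking.

    Per channel: an asymmetric tracker estimates the slowly varying
    noise floor of the medium-time power; the floor is subtracted and
    the residual rectified. A second tracker of the rectified signal
    provides a re-insertion level for non-excitation frames (floor
    energy instead of hard zero), and temporal masking suppresses
    trailing echoes of strong onsets.
    """
    config = config or PnccConfig()
    q = np.asarray(q, dtype=np.float64)
    floor = _asymmetric_lowpass(q, config.asym_lambda_a, config.asym_lambda_b)
    rect = np.maximum(q - floor, 0.0)
    refloor = _asymmetric_lowpass(rect, config.asym_lambda_a, config.asym_lambda_b)

    out = np.empty_like(q)
    peak = rect[0].copy()
    for m in range(q.shape[0]):
        if m > 0:
            peak = np.maximum(config.masking_lambda * peak, rect[m])
        masked = np.where(
            rect[m] >= config.masking_lambda * peak,
            rect[m],
            config.masking_mu * peak,
        )
        excited = q[m] >= config.excitation_c * refloor[m]
        out[m] = np.where(excited, np.maximum(masked, refloor[m]), refloor[m])
    return out


def spectral_weight_smoothing(
    r: np.ndarray,
    q: np.ndarray,
    p: np.ndarray,
    n_neighbors: int = 4,
) -> np.ndarray:
    """Channel-averaged transfer ratio applied to the raw power.

    S[m, l] = mean over l' in [l-N, l+N] of R/Q (channels where Q is
    negligibly small contribute ratio 0); T = P * S.
    """
    eps = 1e-12 * float(q.max()) if q.max() > 0 else 0.0
    ratio = np.where(q > eps, r / np.where(q > eps, q, 1.0), 0.0)
    n_frames, n_ch = ratio.shape
    s = np.empty_like(ratio)
    for l in range(n_ch):
        lo = max(0, l - n_neighbors)
        hi = min(n_ch, l + n_neighbors + 1)
        s[:, l] = ratio[:, lo:hi].mean(axis=1)
    return p * s


def power_normalize_and_compress(
    t: np.ndarray,
    mu_forget: float = 0.999,
    scale_k: float = 1.0,
    exponent: float = 1.0 / 15.0,
) -> np.ndarray:
    """Divide by a running mean of the channel-averaged power, then compress.

    mu[0] is initialized from the first frame's channel mean (cycles
    are far shorter than the forgetting factor's time constant, so a
    zero start would leave a large transient). Returns
    V = (k * T / mu)^exponent.
    """
    t = np.asarray(t, dtype=np.float64)
    n_frames, n_ch = t.shape
    mu = np.empty(n_frames)
    prev = float(t[0].mean())
    if prev <= 0.0:
        prev = 1e-30
    for m in range(n_frames):
        prev = mu_forget * prev + (1 - mu_forget) * float(t[m].mean())
        mu[m] = prev
    mu = np.maximum(mu, 1e-30)
    u = scale_k * t / mu[:, None]
    return np.power(u, exponent)


def pncc_image(
    cycle: np.ndarray,
    config: Optional[PnccConfig] = None,
    rate: float = WORKING_RATE,
    cycle_id: Optional[str] = None,
) -> PnccImage:
    """Full chain: waveform of one cardiac cycle -> PnccImage."""
    config = config or PnccConfig()
    y = pre_emphasis(cycle, config.preemph_k)
    spectra = adaptive_stft(y, config.n_frames_out)
    n_fft = 2 * (spectra.shape[1] - 1)
    fb = gammatone_filterbank(
        config.n_channels, n_fft, rate, config.fmin_hz, config.fmax_hz
    )
    p = filterbank_power(spectra, fb)
    q = medium_time_power(p, config.smoothing_frames)
    r = asymmetric_noise_suppression(q, config)
    t = spectral_weight_smoothing(r, q, p, config.freq_smooth_n)
    v = power_normalize_and_compress(
        t, config.mu_forget, config.scale_k, config.power_exponent
    )
    return PnccImage(v, cycle_id)


def cepstral_coefficients(image: PnccImage, n_coeffs: int = 13) -> np.ndarray:
    """Optional DCT export: conventional cepstral coefficients per frame."""
    return dct(image.values, type=2, norm="ortho", axis=1)[:, :n_coeffs]
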