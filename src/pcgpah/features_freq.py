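"""Frequency-domain features of cardiac cycles and S2 components.

Global spectral shape is summarised on a fixed-length zero-padded DFT
(256 points for the cycle, 512 for S2; zero padding refines the bin
spacing): spectral entropy, the frequency center point (spectral
centroid) and the peak frequency. Pitch-like structure is summarised
framewise over the whole segment: fundamental-frequency statistics
from an autocorrelation estimator, and the deduplicated set of
dominant frequencies (per-frame power-spectral-density peaks).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.signal import find_peaks
from scipy.signal.windows import hamming

FREQ_FEATURE_COLUMNS = (
    "es_cc", "c_cc", "pf_cc", "af_cc", "minf_cc", "maxf_cc",
    "ad_cc", "mind_cc", "maxd_cc", "dd_cc",
    "es_s2", "c_s2", "pf_s2", "af_s2", "minf_s2", "maxf_s2",
    "ad_s2", "mind_s2", "maxd_s2", "dd_s2",
)


@dataclass
class FreqFeatures:
    es_cc: float; c_cc: float; pf_cc: float
    af_cc: float; minf_cc: float; maxf_cc: float
    ad_cc: float; mind_cc: float; maxd_cc: float; dd_cc: float
    es_s2: float; c_s2: float; pf_s2: float
    af_s2: float; minf_s2: float; maxf_s2: float
    ad_s2: float; mind_s2: float; maxd_s2: float; dd_s2: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in FREQ_FEATURE_COLUMNS}


def zero_padded_spectrum(
    segment: np.ndarray, n_points: int, truncate: bool = True
) -> np.ndarray:
    """Magnitude spectrum (DC + positive half) of a zero-padded DFT.

    Segments shorter than ``n_points`` are zero-padded at the tail;
    longer segments are truncated (the framewise paths below cover the
    full signal). Returns ``n_points // 2 + 1`` magnitudes.
    """
    segment = np.asarray(segment, dtype=np.float64)
    if segment.size == 0:
        raise ValueError("empty segment")
    if segment.size > n_points:
        if not truncate:
            raise ValueError(f"segment of {segment.size} exceeds {n_points} points")
        segment = segment[:n_points]
    return np.abs(np.fft.rfft(segment, n=n_points))


def spectral_summary(
    spectrum: np.ndarray, rate: float
) -> Tuple[float, float, float]:
    """Entropy (bits), frequency center (Hz) and peak frequency (Hz).

    The power distribution is the squared magnitude normalized to unit
    sum; entropy is Shannon entropy of that distribution, the center is
    its mean frequency, and the peak is the frequency of the strongest
    non-DC bin. An all-zero spectrum returns (0, 0, 0).
    """
    spectrum = np.asarray(spectrum, dtype=np.float64)
    if spectrum.size == 0 or np.any(spectrum < 0):
        raise ValueError("spectrum must be non-empty and non-negative")
    power = spectrum**2
    total = power.sum()
    if total <= 0.0:
        return 0.0, 0.0, 0.0
    p = power / total
    nz = p[p > 0]
    entropy = float(-np.sum(nz * np.log2(nz)))
    freqs = np.linspace(0, rate / 2, spectrum.size)
    center = float(np.sum(freqs * p))
    peak = float(freqs[1 + int(np.argmax(spectrum[1:]))]) if spectrum.size > 1 else 0.0
    return entropy, center, peak


def _frame_signal(x: np.ndarray, frame_len: int, hop: int) -> np.ndarray:
    n = 1 + max(0, (x.size - frame_len)) // hop
    idx = np.arange(frame_len)[None, :] + hop * np.arange(n)[:, None]
    return x[idx]


def _autocorr_f0(
    frame: np.ndarray,
    rate: float,
    f_lo: float,
    f_hi: float,
    voicing_threshold: float,
) -> Optional[float]:
    """Fundamental frequency of one frame, or None when unvoiced.

    Normalized autocorrelation peak search in the lag band matching
    [f_lo, f_hi]; a frame is voiced when the peak exceeds the
    threshold. Parabolic interpolation refines the lag.
    """
    frame = frame - frame.mean()
    r0 = float(np.dot(frame, frame))
    if r0 <= 0.0:
        return None
    r = np.correlate(frame, frame, mode="full")[frame.size - 1 :] / r0
    lag_min = max(2, int(np.floor(rate / f_hi)))
    lag_max = min(frame.size - 2, int(np.ceil(rate / f_lo)))
    if lag_max <= lag_min:
        return None
    band = r[lag_min : lag_max + 1]
    # pitch period = a local maximum of the autocorrelation; a plain
    # argmax would pick the short-lag shoulder of the lag-0 peak
    peaks, _ = find_peaks(band)
    if peaks.size == 0:
        return None
    k = int(peaks[np.argmax(band[peaks])]) + lag_min
    if r[k] < voicing_threshold:
        return None
    # parabolic refinement around the integer-lag peak
    y0, y1, y2 = r[k - 1], r[k], r[k + 1]
    denom = y0 - 2 * y1 + y2
    delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
    return float(rate / (k + np.clip(delta, -0.5, 0.5)))


def fundamental_stats(
    segment: np.ndarray,
    rate: float,
    frame_s: float = 0.05,
    f_lo: float = 20.0,
    f_hi: float = 400.0,
    voicing_threshold: float = 0.3,
    energy_floor_rel: float = 1e-3,
) -> Tuple[float, float, float, bool]:
    """Mean/min/max fundamental frequency over voiced frames.

    Frames (50% overlap) below a relative energy floor or failing the
    voicing test contribute nothing; if no frame yields an estimate,
    all three statistics are 0 and the result is flagged.
    """
    segment = np.asarray(segment, dtype=np.float64)
    frame_len = int(round(frame_s * rate))
    hop = max(1, frame_len // 2)
    if segment.size < 2 * frame_len:
        return 0.0, 0.0, 0.0, True
    frames = _frame_signal(segment, frame_len, hop)
    energies = np.mean(frames**2, axis=1)
    floor = energy_floor_rel * float(energies.max()) if energies.max() > 0 else 0.0
    estimates = []
    for frame, e in zip(frames, energies):
        if e <= floor:
            continue
        f0 = _autocorr_f0(frame, rate, f_lo, f_hi, voicing_threshold)
        if f0 is not None:
            estimates.append(f0)
    if not estimates:
        return 0.0, 0.0, 0.0, True
    arr = np.asarray(estimates)
    return float(arr.mean()), float(arr.min()), float(arr.max()), False


def dominant_frequencies(
    segment: np.ndarray,
    rate: float,
    frame_s: float = 0.05,
    prominence_rel: float = 0.05,
) -> Tuple[np.ndarray, float, float, float, float, bool]:
    """Deduplicated per-frame PSD peak frequencies and their statistics.

    Each Hamming-windowed frame's periodogram is scanned for peaks at
    least ``prominence_rel`` of that frame's maximum power; pooled
    peak frequencies are deduplicated at DFT-bin resolution. Returns
    ``(unique_freqs, mean, min, max, range, flagged)``.
    """
    segment = np.asarray(segment, dtype=np.float64)
    frame_len = int(round(frame_s * rate))
    hop = max(1, frame_len // 2)
    if segment.size < frame_len:
        frames = segment[None, :]
        frame_len = segment.size
    else:
        frames = _frame_signal(segment, frame_len, hop)
    window = hamming(frame_len, sym=False)
    freqs = np.fft.rfftfreq(frame_len, d=1.0 / rate)
    bins: set[int] = set()
    for frame in frames:
        psd = np.abs(np.fft.rfft(frame * window)) ** 2
        if psd.max() <= 0:
            continue
        peaks, _ = find_peaks(psd, height=prominence_rel * float(psd.max()))
        bins.update(int(p) for p in peaks)
    if not bins:
        return np.array([]), 0.0, 0.0, 0.0, 0.0, True
    uniq = freqs[sorted(bins)]
    return (
        uniq,
        float(uniq.mean()),
        float(uniq.min()),
        float(uniq.max()),
        float(uniq.max() - uniq.min()),
        False,
    )


def assemble_freq_features(
    cycle: np.ndarray,
    s2: np.ndarray,
    rate: float,
    n_points_cc: int = 256,
    n_points_s2: int = 512,
    frame_s: float = 0.05,
) -> FreqFeatures:
    """Populate the full frequency-domain feature row for one cycle.

    Entropy/center/peak use the fixed-length DFT; fundamental and
    dominant-frequency statistics run framewise over the whole segment.
    """
    out = {}
    for name, seg, n_pts in (("cc", cycle, n_points_cc), ("s2", s2, n_points_s2)):
        spec = zero_padded_spectrum(seg, n_pts)
        es, c, pf = spectral_summary(spec, rate)
        af, minf, maxf, _ = fundamental_stats(seg, rate, frame_s)
        _, ad, mind, maxd, dd, _ = dominant_frequencies(seg, rate, frame_s)
        out.update({
            f"es_{name}": es, f"c_{name}": c, f"pf_{name}": pf,
            f"af_{name}": af, f"minf_{name}": minf, f"maxf_{name}": maxf,
            f"ad_{name}": ad, f"mind_{name}": mind, f"maxd_{name}": maxd,
            f"dd_{name}": dd,
        })
    return FreqFeatures(**out)
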