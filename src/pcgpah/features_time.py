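"""Time-domain features of a cardiac cycle and its S2 component.

Pulmonary hypertension loudens and splits the second heart sound, so
the feature set emphasises S2: intensities (sum of squared amplitude)
of the cycle and of S2 and their ratio, durations and their ratio, the
largest and second-largest envelope peaks, and the phase (time)
difference between them — on S2 this difference tracks the A2-P2
split.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional, Tuple

import numpy as np
from scipy.signal import find_peaks

TIME_FEATURE_COLUMNS = (
    "i_cc", "i_s2", "i_ratio",
    "l_cc", "l_s2", "l_ratio",
    "m_cc", "m2_cc", "pos_cc",
    "m_s2", "m2_s2", "pos_s2",
)


@dataclass
class TimeFeatures:
    i_cc: float
    i_s2: float
    i_ratio: float
    l_cc: float
    l_s2: float
    l_ratio: float
    m_cc: float
    m2_cc: float
    pos_cc: float
    m_s2: float
    m2_s2: float
    pos_s2: float
    second_peak_missing_cc: bool = False
    second_peak_missing_s2: bool = False

    def as_dict(self, include_pos_cc: bool = True) -> dict:
        d = {k: getattr(self, k) for k in TIME_FEATURE_COLUMNS}
        if not include_pos_cc:
            d.pop("pos_cc")
        return d


def intensity(segment: np.ndarray) -> float:
    """Heart-sound intensity: the plain sum of squared amplitudes."""
    segment = np.asarray(segment, dtype=np.float64)
    if segment.size == 0:
        raise ValueError("empty segment")
    return float(np.sum(segment**2))


def _smoothed_envelope(segment: np.ndarray, rate: float, smooth_ms: float) -> np.ndarray:
    """Rectified waveform smoothed with a short moving average."""
    env = np.abs(np.asarray(segment, dtype=np.float64))
    win = max(1, int(round(smooth_ms * 1e-3 * rate)))
    if win > 1:
        env = np.convolve(env, np.ones(win) / win, mode="same")
    return env


def peak_pair(
    segment: np.ndarray,
    rate: float,
    min_sep_ms: float = 20.0,
    smooth_ms: float = 10.0,
) -> Tuple[float, float, float, bool]:
    """Largest and second-largest morphological peaks of a segment.

    Peaks are found on the rectified, 10 ms-smoothed envelope with a
    minimum separation so that the two peaks are distinct acoustic
    events (e.g. A2 and P2) rather than adjacent samples of one
    oscillation.

    Returns ``(max_val, second_max_val, phase_diff_s, flagged)``;
    when no second peak satisfies the separation, ``second_max_val`` is
    0, ``phase_diff_s`` is 0 and ``flagged`` is True.
    """
    segment = np.asarray(segment, dtype=np.float64)
    min_sep = max(1, int(round(min_sep_ms * 1e-3 * rate)))
    if segment.size <= 2 * min_sep:
        raise ValueError("segment too short for the requested peak separation")
    env = _smoothed_envelope(segment, rate, smooth_ms)
    t_max = int(np.argmax(env))
    max_val = float(env[t_max])
    peaks, _ = find_peaks(env, distance=min_sep)
    candidates = peaks[np.abs(peaks - t_max) >= min_sep]
    if candidates.size == 0:
        return max_val, 0.0, 0.0, True
    second = int(candidates[np.argmax(env[candidates])])
    return max_val, float(env[second]), abs(second - t_max) / rate, False


def assemble_time_features(
    cycle: np.ndarray,
    s2: np.ndarray,
    rate: float,
    min_sep_ms: float = 20.0,
) -> TimeFeatures:
    """Populate the full time-domain feature row for one cycle."""
    cycle = np.asarray(cycle, dtype=np.float64)
    s2 = np.asarray(s2, dtype=np.float64)
    i_cc = intensity(cycle)
    i_s2 = intensity(s2)
    if i_cc == 0.0:
        raise ValueError("silent cycle: intensity ratio undefined")
    m_cc, m2_cc, pos_cc, miss_cc = peak_pair(cycle, rate, min_sep_ms)
    m_s2, m2_s2, pos_s2, miss_s2 = peak_pair(s2, rate, min_sep_ms)
    return TimeFeatures(
        i_cc=i_cc,
        i_s2=i_s2,
        i_ratio=i_s2 / i_cc,
        l_cc=cycle.size / rate,
        l_s2=s2.size / rate,
        l_ratio=s2.size / cycle.size,
        m_cc=m_cc,
        m2_cc=m2_cc,
        pos_cc=pos_cc,
        m_s2=m_s2,
        m2_s2=m2_s2,
        pos_s2=pos_s2,
        second_peak_missing_cc=miss_cc,
        second_peak_missing_s2=miss_s2,
    )
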