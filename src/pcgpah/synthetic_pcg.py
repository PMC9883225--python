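"""Synthetic phonocardiograms with exact ground-truth annotations.

Clinical CHD-PAH heart-sound data cannot be redistributed, so every
stage of the pipeline is exercised on simulated records. A record is a
train of quasi-periodic cardiac cycles; each cycle contains an S1
burst, a systolic interval (with a band-limited murmur for the CHD
classes), an S2 burst and a diastolic interval. Bursts are
Gaussian-enveloped, slightly downward-gliding tones — morphologically
closer to valve-closure transients than pure sinusoids. Class identity
enters through S2 morphology, mirroring auscultation: pulmonary
hypertension loudens S2 and splits it into separated aortic (A2) and
pulmonic (P2) lobes.

The simulator emulates the signal properties the method assumes
(quasi-periodicity, S2-concentrated pathology, content below 1 kHz);
it does not model hemodynamics, respiration-modulated splitting or
recording-site variation, so results on it bound algorithmic
correctness, not clinical performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .audio_io import CLASS_ORDER, WORKING_RATE, AudioRecord, save_record
from .segmentation import CycleAnnotation, SegmentInterval


@dataclass
class BurstSpec:
    """One Gaussian-enveloped chirp burst."""

    center_freq_hz: float
    duration_ms: float
    amplitude: float
    chirp_down: float = 0.15  # fractional downward frequency glide


@dataclass
class SyntheticSpec:
    """Generation parameters for one synthetic record."""

    class_label: str = "Normal"
    heart_rate_bpm: float = 75.0
    record_s: float = 20.0
    sample_rate: int = WORKING_RATE
    s1: BurstSpec = field(default_factory=lambda: BurstSpec(45.0, 120.0, 1.0))
    s2: BurstSpec = field(default_factory=lambda: BurstSpec(70.0, 100.0, 0.8))
    split_ms: float = 0.0  # A2-P2 delay
    p2_rel_amp: float = 0.0
    murmur_band_hz: Tuple[float, float] = (150.0, 400.0)
    murmur_level: float = 0.0  # amplitude of systolic murmur noise
    noise_snr_db: float = 15.0
    cycle_jitter: float = 0.03  # fractional period jitter
    systole_frac: float = 0.35  # systole share of the cycle (S1 start -> S2 start)
    seed: int = 0

    def validate(self) -> None:
        if self.class_label not in CLASS_ORDER:
            raise ValueError(f"unknown class {self.class_label!r}")
        if self.split_ms > 0 and self.split_ms >= 2.0 * self.s2.duration_ms:
            raise ValueError("A2-P2 split exceeds the S2 burst it must fit in")
        if not 0.3 <= 60.0 / self.heart_rate_bpm <= 1.5:
            raise ValueError("heart rate outside supported cycle-period range")


#: Class-dependent S2 morphology: (split_ms, p2_rel_amp, s2_amp_scale, murmur_level)
CLASS_PRESETS: Dict[str, Tuple[float, float, float, float]] = {
    "Normal": (0.0, 0.0, 1.0, 0.0),
    "CHD": (15.0, 0.7, 1.15, 0.05),
    "CHD-PAH": (40.0, 0.8, 1.6, 0.04),
}


def spec_for_class(class_label: str, seed: int = 0, **overrides) -> SyntheticSpec:
    """Default generation spec for a diagnostic class."""
    split, p2, s2_scale, murmur = CLASS_PRESETS[class_label]
    base = SyntheticSpec(class_label=class_label, seed=seed)
    s2 = replace(base.s2, amplitude=base.s2.amplitude * s2_scale)
    spec = replace(
        base, s2=s2, split_ms=split, p2_rel_amp=p2, murmur_level=murmur, **overrides
    )
    return spec


@dataclass
class GroundTruth:
    """Exact per-cycle intervals; intervals tile each cycle."""

    cycles: List[CycleAnnotation]
    class_label: str


def _burst(
    rng: np.random.Generator,
    burst: BurstSpec,
    rate: int,
    amplitude_scale: float = 1.0,
) -> np.ndarray:
    """Gaussian-windowed downward chirp; support is exactly duration_ms."""
    n = int(round(burst.duration_ms * 1e-3 * rate))
    t = np.arange(n) / rate
    dur = n / rate
    sigma = dur / 5.0
    env = np.exp(-0.5 * ((t - dur / 2) / sigma) ** 2)
    f0 = burst.center_freq_hz
    f1 = f0 * (1.0 - burst.chirp_down)
    phase = 2 * np.pi * (f0 * t + (f1 - f0) * t**2 / (2 * dur))
    phi = rng.uniform(0, 2 * np.pi)
    return burst.amplitude * amplitude_scale * env * np.sin(phase + phi)


def _bandlimited_noise(
    rng: np.random.Generator, n: int, rate: int, band: Tuple[float, float]
) -> np.ndarray:
    """Unit-variance noise band-passed to ``band`` (zero-phase filter)."""
    raw = rng.standard_normal(n + 200)
    nyq = rate / 2
    sos = butter(4, [band[0] / nyq, band[1] / nyq], btype="band", output="sos")
    out = sosfiltfilt(sos, raw)[100:-100]
    std = out.std()
    return out / std if std > 0 else out


def _add_at(x: np.ndarray, start: int, burst: np.ndarray) -> None:
    end = min(start + burst.size, x.size)
    if end > start:
        x[start:end] += burst[: end - start]


def generate_record(
    spec: SyntheticSpec, record_id: Optional[str] = None
) -> Tuple[AudioRecord, GroundTruth]:
    """Synthesize one record and its exact ground-truth annotation.

    Fully determined by ``spec.seed``. Additive broadband noise is
    low-passed below 1 kHz so the record obeys the band-limit premise
    of the working rate.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rate = spec.sample_rate
    n_total = int(round(spec.record_s * rate))
    x = np.zeros(n_total)
    cycles: List[CycleAnnotation] = []

    period_nominal = 60.0 / spec.heart_rate_bpm
    s1_len = int(round(spec.s1.duration_ms * 1e-3 * rate))
    s2_len = int(round(spec.s2.duration_ms * 1e-3 * rate)) + int(
        round(spec.split_ms * 1e-3 * rate)
    )

    onset = 0
    while True:
        period_s = period_nominal * (1.0 + spec.cycle_jitter * rng.uniform(-1, 1))
        period = int(round(period_s * rate))
        if onset + period > n_total:
            break
        s2_on = onset + int(round(spec.systole_frac * period))
        # S1 burst
        _add_at(x, onset, _burst(rng, spec.s1, rate))
        # S2 burst: A2 lobe (+ delayed P2 lobe when split)
        a2 = _burst(rng, spec.s2, rate)
        _add_at(x, s2_on, a2)
        if spec.split_ms > 0 and spec.p2_rel_amp > 0:
            delay = int(round(spec.split_ms * 1e-3 * rate))
            p2 = _burst(rng, spec.s2, rate, amplitude_scale=spec.p2_rel_amp)
            _add_at(x, s2_on + delay, p2)
        # systolic murmur for CHD classes
        if spec.murmur_level > 0:
            murmur_span = (onset + s1_len, s2_on)
            if murmur_span[1] > murmur_span[0]:
                m = _bandlimited_noise(
                    rng, murmur_span[1] - murmur_span[0], rate, spec.murmur_band_hz
                )
                x[murmur_span[0] : murmur_span[1]] += spec.murmur_level * m

        cycle_end = min(onset + period, n_total)
        cycles.append(
            CycleAnnotation(
                s1=SegmentInterval(onset, onset + s1_len, "S1"),
                systole=SegmentInterval(onset + s1_len, s2_on, "systole"),
                s2=SegmentInterval(s2_on, s2_on + s2_len, "S2"),
                diastole=SegmentInterval(s2_on + s2_len, cycle_end, "diastole"),
            )
        )
        onset += period

    # additive broadband noise, low-passed below 1 kHz, at the requested SNR
    signal_power = float(np.mean(x**2))
    if np.isfinite(spec.noise_snr_db) and signal_power > 0:
        noise = _bandlimited_noise(rng, n_total, rate, (5.0, 995.0))
        noise_power = signal_power / (10.0 ** (spec.noise_snr_db / 10.0))
        x = x + noise * np.sqrt(noise_power)

    peak = np.max(np.abs(x))
    if peak > 0:
        x = 0.95 * x / peak
    rid = record_id or f"{spec.class_label.lower()}-{spec.seed}"
    record = AudioRecord(rid, x, rate, spec.class_label)
    return record, GroundTruth(cycles, spec.class_label)


def generate_dataset(
    n_per_class: int,
    seed: int = 0,
    classes: Sequence[str] = CLASS_ORDER,
    record_s: float = 20.0,
    noise_snr_db: float = 15.0,
) -> Tuple[List[AudioRecord], List[GroundTruth], pd.DataFrame]:
    """Balanced labeled corpus with per-record heart-rate/seed jitter.

    Returns (records, ground truths, manifest). The manifest has
    columns (record_id, label) and aligns with the record list; two
    calls with the same arguments are identical.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    records, truths, rows = [], [], []
    for label in classes:
        for i in range(n_per_class):
            rec_seed = int(rng.integers(0, 2**31 - 1))
            hr = float(rng.uniform(60.0, 100.0))
            spec = spec_for_class(
                label,
                seed=rec_seed,
                heart_rate_bpm=hr,
                record_s=record_s,
                noise_snr_db=noise_snr_db,
            )
            rid = f"{label.lower().replace('-', '')}-{i:03d}"
            rec, truth = generate_record(spec, record_id=rid)
            records.append(rec)
            truths.append(truth)
            rows.append({"record_id": rid, "label": label})
    return records, truths, pd.DataFrame(rows)


def write_dataset(
    records: Sequence[AudioRecord],
    truths: Sequence[GroundTruth],
    manifest: pd.DataFrame,
    out_dir: str | Path,
) -> Path:
    """Write WAVs, ground-truth CSV and a manifest CSV under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    gt_rows = []
    for rec, truth in zip(records, truths):
        path = save_record(rec, out_dir / f"{rec.record_id}.wav")
        paths.append(str(path))
        for k, ann in enumerate(truth.cycles):
            for part in ("s1", "systole", "s2", "diastole"):
                iv = getattr(ann, part)
                gt_rows.append(
                    {
                        "record_id": rec.record_id,
                        "cycle_index": k,
                        "label": iv.label,
                        "start_s": iv.start / rec.sample_rate,
                        "end_s": iv.end / rec.sample_rate,
                    }
                )
    manifest = manifest.copy()
    manifest["path"] = paths
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    pd.DataFrame(gt_rows).to_csv(out_dir / "ground_truth.csv", index=False)
    return out_dir / "manifest.csv"
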