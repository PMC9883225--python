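"""WAV input/output and rate conversion for heart-sound records.

Clinical phonocardiograms are captured by electronic stethoscopes as
single-channel PCM audio; diagnostically relevant content sits below
1 kHz, so the pipeline operates at a working rate of 2500 Hz and
recordings at higher rates are decimated with an anti-aliasing FIR
filter on load.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

WORKING_RATE = 2500
#: Recognised diagnostic classes, in canonical order (used for tie-breaks).
CLASS_ORDER = ("Normal", "CHD", "CHD-PAH")


@dataclass
class AudioRecord:
    """A single-channel heart-sound recording.

    Parameters
    ----------
    record_id
        Stable identifier carried through annotations and feature tables.
    samples
        Float amplitude in approximately [-1, 1].
    sample_rate
        Sampling rate in Hz.
    label
        Optional diagnostic class, one of :data:`CLASS_ORDER`.
    """

    record_id: str
    samples: np.ndarray
    sample_rate: int
    label: Optional[str] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("AudioRecord requires mono (1-D) samples")
        if self.samples.size == 0:
            raise ValueError("AudioRecord requires non-empty samples")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.label is not None and self.label not in CLASS_ORDER:
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate

    def normalized(self) -> "AudioRecord":
        """Scale so max |amplitude| is 1 (no-op on silent records)."""
        peak = float(np.max(np.abs(self.samples)))
        if peak == 0.0:
            return self
        return replace(self, samples=self.samples / peak)


def load_record(
    path: str | Path,
    expect_rate: Optional[int] = None,
    record_id: Optional[str] = None,
    allow_stereo_mixdown: bool = False,
) -> AudioRecord:
    """Read a mono WAV file into an :class:`AudioRecord`.

    Integer PCM is rescaled to float in [-1, 1]. Stereo files are
    rejected unless ``allow_stereo_mixdown`` is set, in which case
    channels are averaged. A metadata sidecar ``<path>.json`` written by
    :func:`save_record` is honoured for ``record_id`` and ``label``.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except (FileNotFoundError, ValueError) as exc:
        raise IOError(f"cannot read WAV file {path}: {exc}") from exc
    if data.size == 0:
        raise IOError(f"zero-length audio in {path}")
    if data.ndim == 2:
        if not allow_stereo_mixdown:
            raise IOError(
                f"{path} is multi-channel; stethoscope recordings are mono "
                "(pass allow_stereo_mixdown=True to average channels)"
            )
        data = data.mean(axis=1)
    if expect_rate is not None and rate != expect_rate:
        raise IOError(f"{path}: sample rate {rate} != expected {expect_rate}")

    if np.issubdtype(data.dtype, np.integer):
        # symmetric with save_record's scaling (full-scale = iinfo.max)
        samples = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
    else:
        samples = data.astype(np.float64)
    if not np.all(np.isfinite(samples)):
        raise IOError(f"{path} contains non-finite samples")

    label = None
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        record_id = record_id or meta.get("record_id")
        label = meta.get("label")
    return AudioRecord(record_id or path.stem, samples, int(rate), label)


def save_record(record: AudioRecord, path: str | Path, sidecar: bool = True) -> Path:
    """Write a record as 16-bit PCM WAV with a JSON metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    clipped = np.clip(record.samples, -1.0, 1.0)
    pcm = np.round(clipped * 32767.0).astype(np.int16)
    wavfile.write(path, record.sample_rate, pcm)
    if sidecar:
        meta = {
            "record_id": record.record_id,
            "label": record.label,
            "sample_rate": record.sample_rate,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))
    return path


def resample_to_working_rate(
    record: AudioRecord,
    target: int = WORKING_RATE,
    allow_upsample: bool = False,
) -> AudioRecord:
    """Decimate a record to the working rate with polyphase FIR filtering.

    The usual case (5000 Hz clinical capture) is an exact rational
    factor of 1/2. Upsampling is refused unless explicitly enabled,
    since it fabricates no new information.
    """
    if record.sample_rate == target:
        return record
    if record.sample_rate < target and not allow_upsample:
        raise ValueError(
            f"record rate {record.sample_rate} below target {target}; "
            "pass allow_upsample=True to force"
        )
    frac = Fraction(target, record.sample_rate).limit_denominator(1000)
    out = resample_poly(record.samples, frac.numerator, frac.denominator)
    expected = math.ceil(record.samples.size * target / record.sample_rate)
    # resample_poly may pad by a sample; trim to preserve duration.
    out = out[:expected]
    return replace(record, samples=out, sample_rate=target)
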