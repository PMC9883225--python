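"""Adaptive segmentation of heart sounds into S1/systole/S2/diastole.

The segmenter follows the double-threshold endpoint-detection scheme:
non-overlapping 0.1 s frames yield two envelopes — short-time energy
and spectral spread (the standard deviation of the frame spectrum about
its centroid, in Hz). Each envelope's histogram is bimodal on a typical
record (quiet systole/diastole frames vs. loud S1/S2 frames); a
threshold is placed between the two modes as a weighted mean

    T = (W * M1 + M2) / (W + 1)

where M1 and M2 are the positions (lower, higher) of the histogram's
two tallest local maxima and W biases the threshold toward the mode
whose frames the criterion rejects, the sensitive setting.
Frames passing both the energy criterion (E >= T_E) and
the spread criterion are candidate heart-sound components; candidate
runs closer than a merge distance (50 ms) are fused, component edges
are optionally refined at 10 ms resolution, and components are labeled
S1/S2 using the physiological rule that diastole is the longest
interval between adjacent components.

Heart sounds concentrate their energy at low frequency, so components
have a *small* spectral spread while broadband noise frames have a
large one; the spread criterion therefore selects frames with
S <= T_S by default (``spread_direction="below"``). The opposite
direction is available for experimentation (``"above"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Literal, Optional, Sequence, Tuple

import numpy as np
from scipy.signal.windows import hamming

from .audio_io import WORKING_RATE, AudioRecord

Label = Literal["S1", "systole", "S2", "diastole", "component"]


@dataclass
class EnvelopeSequence:
    """Per-frame short-time energy and spectral spread."""

    energies: np.ndarray  # mean squared amplitude per frame
    spreads: np.ndarray  # Hz, std of spectrum about its centroid
    frame_len: int  # samples
    hop: int  # samples
    sample_rate: int

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=np.float64)
        self.spreads = np.asarray(self.spreads, dtype=np.float64)
        if self.energies.shape != self.spreads.shape:
            raise ValueError("energy/spread length mismatch")

    @property
    def n_frames(self) -> int:
        return self.energies.size


@dataclass
class ThresholdResult:
    value: float
    m1: Optional[float] = None  # position of the lower-lying mode
    m2: Optional[float] = None
    fallback: bool = False  # True when < 2 histogram maxima were found


@dataclass
class ThresholdPair:
    energy: ThresholdResult
    spread: ThresholdResult


@dataclass(frozen=True)
class SegmentInterval:
    """Half-open sample interval [start, end) with a physiological label."""

    start: int
    end: int
    label: Label = "component"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    @property
    def n_samples(self) -> int:
        return self.end - self.start

    def duration_s(self, rate: int = WORKING_RATE) -> float:
        return self.n_samples / rate


@dataclass(frozen=True)
class CycleAnnotation:
    """One cardiac cycle: contiguous S1 -> systole -> S2 -> diastole."""

    s1: SegmentInterval
    systole: SegmentInterval
    s2: SegmentInterval
    diastole: SegmentInterval

    def __post_init__(self) -> None:
        seq = (self.s1, self.systole, self.s2, self.diastole)
        for a, b in zip(seq, seq[1:]):
            if a.end != b.start:
                raise ValueError("cycle intervals must be contiguous")

    @property
    def start(self) -> int:
        return self.s1.start

    @property
    def end(self) -> int:
        return self.diastole.end

    def duration_s(self, rate: int = WORKING_RATE) -> float:
        return (self.end - self.start) / rate


def frame_energy(frame: np.ndarray) -> float:
    """Mean squared amplitude of one frame (rectangular window)."""
    frame = np.asarray(frame, dtype=np.float64)
    return float(np.mean(np.abs(frame) ** 2))


def frame_spectral_spread(frame: np.ndarray, rate: int) -> float:
    """Std (Hz) of the Hamming-windowed frame spectrum about its centroid.

    The spectral distribution is power-weighted (squared magnitude):
    power weighting lets a strong narrowband transient dominate the
    centroid even over a broadband noise floor, which is exactly the
    contrast the segmenter exploits. An all-zero frame has no
    spectrum; its spread is 0 by convention.
    """
    frame = np.asarray(frame, dtype=np.float64)
    power = np.abs(np.fft.rfft(frame * hamming(frame.size, sym=False))) ** 2
    total = power.sum()
    if total <= 0.0:
        return 0.0
    freqs = np.fft.rfftfreq(frame.size, d=1.0 / rate)
    centroid = float(np.sum(freqs * power) / total)
    var = float(np.sum((freqs - centroid) ** 2 * power) / total)
    return float(np.sqrt(var))


def compute_envelopes(
    record: AudioRecord,
    window_s: float = 0.1,
    hop_s: Optional[float] = None,
) -> EnvelopeSequence:
    """Frame a record and compute energy/spread envelopes.

    Frames are non-overlapping by default (hop == window); a trailing
    partial frame is discarded.
    """
    frame_len = int(round(window_s * record.sample_rate))
    hop = frame_len if hop_s is None else int(round(hop_s * record.sample_rate))
    if frame_len < 1 or hop < 1:
        raise ValueError("window/hop too short")
    x = record.samples
    if x.size < frame_len:
        raise ValueError("record shorter than one analysis frame")
    n_frames = 1 + (x.size - frame_len) // hop
    energies = np.empty(n_frames)
    spreads = np.empty(n_frames)
    for i in range(n_frames):
        frame = x[i * hop : i * hop + frame_len]
        energies[i] = frame_energy(frame)
        spreads[i] = frame_spectral_spread(frame, record.sample_rate)
    return EnvelopeSequence(energies, spreads, frame_len, hop, record.sample_rate)


def threshold_from_maxima(m1: float, m2: float, weight: float) -> float:
    """Weighted mean of two histogram mode positions.

    ``weight = 0`` returns ``m2``; as ``weight`` grows the threshold
    approaches ``m1`` (the mode at the lower position), the sensitive
    setting.
    """
    return (weight * m1 + m2) / (weight + 1.0)


def _histogram_local_maxima(
    values: np.ndarray, n_bins: int, smooth: int = 3
) -> Tuple[np.ndarray, np.ndarray]:
    """Bin centers and smoothed counts of local maxima, ordered by position."""
    counts, edges = np.histogram(values, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    # running mean whose window shrinks at the edges: zero-padding would
    # bias the first mode's position away from the histogram boundary
    half = smooth // 2
    sm = np.array(
        [
            counts[max(0, i - half) : i + half + 1].mean()
            for i in range(counts.size)
        ],
        dtype=float,
    )
    is_max = np.zeros(sm.size, dtype=bool)
    for i in range(sm.size):
        left = sm[i - 1] if i > 0 else -np.inf
        right = sm[i + 1] if i < sm.size - 1 else -np.inf
        # strictly above the left neighbour, at-least-equal on the right:
        # plateaus count once, at their leading edge
        is_max[i] = sm[i] > left and sm[i] >= right and sm[i] > 0
    return centers[is_max], sm[is_max]


def adaptive_threshold(
    values: Sequence[float],
    weight: float = 5.0,
    n_bins: int = 50,
    bias: Literal["low", "high"] = "low",
) -> ThresholdResult:
    """Place a detection threshold between the two main histogram modes.

    The histogram's two tallest local maxima (after 3-bin smoothing)
    are taken as the mode positions; M1 is the lower-lying and M2 the
    higher-lying of the two. The threshold is their weighted mean,
    ``T = (W*M1 + M2)/(W + 1)`` with ``bias="low"`` — the sensitive
    setting for an at-least-threshold criterion — or the mirror image
    ``T = (M1 + W*M2)/(W + 1)`` with ``bias="high"``, the sensitive
    setting for an at-most-threshold criterion.

    Falls back to ``mean + 0.5 * std`` (flagged) when the smoothed
    histogram exposes fewer than two local maxima.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("empty value sequence")
    if n_bins < 3:
        raise ValueError("n_bins must be >= 3")
    positions, heights = _histogram_local_maxima(values, n_bins)
    if positions.size < 2:
        return ThresholdResult(
            value=float(values.mean() + 0.5 * values.std()), fallback=True
        )
    # two tallest maxima; ties resolved toward the lower position
    order = np.lexsort((positions, -heights))[:2]
    m1, m2 = sorted(float(positions[i]) for i in order)
    if bias == "low":
        t = threshold_from_maxima(m1, m2, weight)
    else:
        t = threshold_from_maxima(m2, m1, weight)
    return ThresholdResult(t, m1, m2)


def estimate_thresholds(
    env: EnvelopeSequence,
    weight: float = 5.0,
    n_bins: int = 50,
    spread_direction: Literal["below", "above"] = "below",
) -> ThresholdPair:
    """Energy and spread thresholds for component detection.

    The energy criterion accepts frames above its threshold, so the
    energy threshold hugs the quiet mode. The spread threshold hugs
    whichever mode the configured direction rejects: with the default
    ``below`` (components are narrowband, low-spread) it sits near the
    broadband-noise mode.
    """
    return ThresholdPair(
        energy=adaptive_threshold(env.energies, weight, n_bins, bias="low"),
        spread=adaptive_threshold(
            env.spreads, weight, n_bins,
            bias="high" if spread_direction == "below" else "low",
        ),
    )


def merge_intervals(
    intervals: Sequence[SegmentInterval],
    merge_gap_samples: int,
) -> List[SegmentInterval]:
    """Fuse sorted intervals whose gap is strictly below the merge distance."""
    if not intervals:
        return []
    merged = [intervals[0]]
    for iv in intervals[1:]:
        prev = merged[-1]
        if iv.start - prev.end < merge_gap_samples:
            merged[-1] = SegmentInterval(prev.start, max(prev.end, iv.end), prev.label)
        else:
            merged.append(iv)
    return merged


def _runs_to_intervals(mask: np.ndarray, hop: int, frame_len: int) -> List[SegmentInterval]:
    """Contiguous True runs of a frame mask, mapped to sample coordinates."""
    out: List[SegmentInterval] = []
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return out
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    for s, e in zip(starts, ends):
        out.append(SegmentInterval(int(idx[s]) * hop, int(idx[e]) * hop + frame_len))
    return out


def _refine_edges(
    record: AudioRecord,
    components: List[SegmentInterval],
    energy_threshold: float,
    resolution_s: float = 0.01,
    context_s: float = 0.1,
    threshold_frac: float = 0.25,
) -> List[SegmentInterval]:
    """Re-locate component edges on a fine (10 ms) energy envelope.

    The coarse 0.1 s frame grid quantizes edges more coarsely than S2
    itself lasts; within each component's neighbourhood the edge is
    moved to the fine-grained run, containing the energy maximum, whose
    frames stay above a fraction of the detection threshold (a 10 ms
    window at a transient's onset holds far less energy than a 0.1 s
    window centred on it, so the full coarse threshold would clip
    onsets).
    """
    fine_threshold = threshold_frac * energy_threshold
    rate = record.sample_rate
    res = max(1, int(round(resolution_s * rate)))
    ctx = int(round(context_s * rate))
    refined: List[SegmentInterval] = []
    for comp in components:
        lo = max(0, comp.start - ctx)
        hi = min(record.samples.size, comp.end + ctx)
        seg = record.samples[lo:hi]
        n_sub = seg.size // res
        if n_sub < 1:
            refined.append(comp)
            continue
        sub = seg[: n_sub * res].reshape(n_sub, res)
        e = np.mean(sub**2, axis=1)
        if e.max() < energy_threshold:
            refined.append(comp)
            continue
        # all fine-resolution runs above the relaxed threshold whose own
        # peak clears the full threshold; one coarse run may hold several
        # bursts (e.g. S1 and S2 bridged by a soft murmur)
        above = e >= fine_threshold
        idx = np.flatnonzero(above)
        breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [idx.size - 1]))
        kept_any = False
        for s_, e_ in zip(starts, ends):
            a, b = int(idx[s_]), int(idx[e_])
            if e[a : b + 1].max() >= energy_threshold:
                refined.append(SegmentInterval(lo + a * res, lo + (b + 1) * res))
                kept_any = True
        if not kept_any:
            refined.append(comp)
    refined.sort(key=lambda iv: iv.start)
    # refinement may butt neighbours together; fuse overlapping/adjacent
    out: List[SegmentInterval] = []
    for iv in refined:
        if out and iv.start <= out[-1].end:
            out[-1] = SegmentInterval(out[-1].start, max(out[-1].end, iv.end))
        else:
            out.append(iv)
    return out


def detect_components(
    env: EnvelopeSequence,
    thresholds: ThresholdPair,
    merge_ms: float = 50.0,
    spread_direction: Literal["below", "above"] = "below",
    record: Optional[AudioRecord] = None,
    refine: bool = True,
) -> List[SegmentInterval]:
    """Detect candidate S1/S2 components from the two envelopes.

    A frame is a candidate when its energy is at least the energy
    threshold AND its spectral spread passes the spread criterion
    (``below``: S <= T_S, the physically motivated default — heart
    sounds are narrowband and low-frequency; ``above``: S >= T_S).
    Candidate runs separated by strictly less than ``merge_ms`` are
    merged. If ``record`` is given and ``refine`` is on, edges are
    re-located at 10 ms resolution and re-merged.
    """
    flag1 = env.energies >= thresholds.energy.value
    if spread_direction == "below":
        flag2 = env.spreads <= thresholds.spread.value
    else:
        flag2 = env.spreads >= thresholds.spread.value
    mask = flag1 & flag2
    gap = int(round(merge_ms * 1e-3 * env.sample_rate))
    comps = merge_intervals(_runs_to_intervals(mask, env.hop, env.frame_len), gap)
    if record is not None and refine and comps:
        comps = merge_intervals(
            _refine_edges(record, comps, thresholds.energy.value), gap
        )
    return comps


class UnsegmentableRecord(ValueError):
    """Raised when a record yields no physiologically consistent cycles."""


def label_components(
    components: Sequence[SegmentInterval],
    record_len: int,
    rate: int = WORKING_RATE,
    min_cycle_s: float = 0.4,
    max_cycle_s: float = 1.5,
) -> List[CycleAnnotation]:
    """Assemble labeled cardiac cycles from detected components.

    Gaps between adjacent components are classified as diastole (long)
    or systole (short) relative to the midpoint of the observed gap
    range — the longest gap is always a diastole, per the rule that
    diastole is the maximum interval between adjacent components (its
    start-side component is S2, end-side S1). A complete cycle is a
    component pair whose pattern reads S1, short gap, S2, long gap,
    next S1, and whose duration lies within physiological bounds;
    components breaking the pattern (e.g. spurious detections) drop
    only the cycles they touch.
    """
    comps = sorted(components, key=lambda c: c.start)
    if len(comps) < 4:
        raise UnsegmentableRecord(f"only {len(comps)} components detected")
    gaps = np.array(
        [comps[i + 1].start - comps[i].end for i in range(len(comps) - 1)],
        dtype=np.float64,
    )
    if np.any(gaps < 0):
        raise UnsegmentableRecord("overlapping components")
    g_min, g_max = float(gaps.min()), float(gaps.max())
    if g_max < 1.2 * max(g_min, 1.0):
        raise UnsegmentableRecord("gap durations do not separate systole/diastole")
    # two-means clustering of gap durations: short cluster = systole,
    # long cluster = diastole (robust to outlier gaps from missed
    # components, unlike a plain min/max midpoint)
    lo, hi = g_min, g_max
    for _ in range(50):
        assign = np.abs(gaps - lo) <= np.abs(gaps - hi)
        new_lo = float(gaps[assign].mean()) if assign.any() else lo
        new_hi = float(gaps[~assign].mean()) if (~assign).any() else hi
        if new_lo == lo and new_hi == hi:
            break
        lo, hi = new_lo, new_hi
    tau = 0.5 * (lo + hi)
    is_diastole = gaps > tau

    cycles: List[CycleAnnotation] = []
    for j in range(len(comps) - 2):
        if is_diastole[j] or not is_diastole[j + 1]:
            continue  # need pattern: systole gap then diastole gap
        s1c, s2c, nxt = comps[j], comps[j + 1], comps[j + 2]
        duration = (nxt.start - s1c.start) / rate
        if not (min_cycle_s <= duration <= max_cycle_s):
            continue
        cycles.append(
            CycleAnnotation(
                s1=SegmentInterval(s1c.start, s1c.end, "S1"),
                systole=SegmentInterval(s1c.end, s2c.start, "systole"),
                s2=SegmentInterval(s2c.start, s2c.end, "S2"),
                diastole=SegmentInterval(s2c.end, min(nxt.start, record_len), "diastole"),
            )
        )
    if not cycles:
        raise UnsegmentableRecord("no physiologically consistent cycles")
    return cycles


def extract_cycles(
    record: AudioRecord, annotations: Sequence[CycleAnnotation]
) -> List[Tuple[np.ndarray, np.ndarray, CycleAnnotation]]:
    """Slice out each cycle's waveform and its S2 sub-segment."""
    out = []
    for ann in annotations:
        cycle = record.samples[ann.start : ann.end]
        s2 = record.samples[ann.s2.start : ann.s2.end]
        out.append((cycle, s2, ann))
    return out


def segment_record(
    record: AudioRecord,
    window_s: float = 0.1,
    weight: float = 5.0,
    n_bins: int = 50,
    merge_ms: float = 50.0,
    spread_direction: Literal["below", "above"] = "below",
    refine: bool = True,
) -> List[CycleAnnotation]:
    """End-to-end segmentation: envelopes -> thresholds -> components -> cycles.

    Raises :class:`UnsegmentableRecord` when no consistent cycle is found.
    """
    env = compute_envelopes(record, window_s)
    thresholds = estimate_thresholds(env, weight, n_bins, spread_direction)
    comps = detect_components(
        env, thresholds, merge_ms, spread_direction, record=record, refine=refine
    )
    return label_components(comps, record.samples.size, record.sample_rate)


def annotations_to_rows(record_id: str, annotations, rate: int = WORKING_RATE):
    """Flatten annotations to (record_id, cycle_index, label, start_s, end_s) rows."""
    rows = []
    for k, ann in enumerate(annotations):
        for label in ("s1", "systole", "s2", "diastole"):
            iv: SegmentInterval = getattr(ann, label)
            rows.append(
                {
                    "record_id": record_id,
                    "cycle_index": k,
                    "label": iv.label,
                    "start_s": iv.start / rate,
                    "end_s": iv.end / rate,
                }
            )
    return rows
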