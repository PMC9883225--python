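"""Envelope oracles, adaptive thresholds, merging and cycle labeling."""

import numpy as np
import pytest
from scipy.signal.windows import hamming

from pcgpah.audio_io import AudioRecord
from pcgpah.segmentation import (
    CycleAnnotation,
    EnvelopeSequence,
    SegmentInterval,
    ThresholdPair,
    ThresholdResult,
    UnsegmentableRecord,
    adaptive_threshold,
    compute_envelopes,
    detect_components,
    extract_cycles,
    frame_energy,
    frame_spectral_spread,
    label_components,
    merge_intervals,
    segment_record,
    threshold_from_maxima,
)
from pcgpah.synthetic_pcg import generate_record, spec_for_class

RATE = 2500


def brute_energy(frame):
    return sum(abs(v) ** 2 for v in frame) / len(frame)


def brute_spread(frame, rate):
    w = hamming(len(frame), sym=False)
    spec = np.fft.rfft(np.asarray(frame) * w)
    s = [abs(v) ** 2 for v in spec]
    total = sum(s)
    if total == 0:
        return 0.0
    freqs = [k * rate / len(frame) for k in range(len(s))]
    mu = sum(f * p for f, p in zip(freqs, s)) / total
    return (sum((f - mu) ** 2 * p for f, p in zip(freqs, s)) / total) ** 0.5


class TestEnvelopes:
    def test_energy_examples(self):
        assert frame_energy([1, -1, 1, -1]) == 1.0
        assert frame_energy(np.zeros(16)) == 0.0

    def test_zero_frame_spread_is_zero(self):
        assert frame_spectral_spread(np.zeros(250), RATE) == 0.0

    def test_pure_tone_spread_within_one_bin(self):
        t = np.arange(250) / RATE
        spread = frame_spectral_spread(np.sin(2 * np.pi * 100 * t), RATE)
        assert spread <= RATE / 250  # one bin width, leakage aside

    def test_envelopes_match_bruteforce(self, normal_record):
        rec, _ = normal_record
        env = compute_envelopes(rec)
        for i in [0, 5, 40, env.n_frames - 1]:
            frame = rec.samples[i * env.hop : i * env.hop + env.frame_len]
            np.testing.assert_allclose(env.energies[i], brute_energy(frame), rtol=1e-9)
            np.testing.assert_allclose(
                env.spreads[i], brute_spread(frame, RATE), rtol=1e-9
            )

    def test_too_short_record_fails(self):
        rec = AudioRecord("x", np.ones(100), RATE)
        with pytest.raises(ValueError):
            compute_envelopes(rec, window_s=0.1)


class TestAdaptiveThreshold:
    def test_formula_and_limits(self):
        assert threshold_from_maxima(2.0, 5.0, 5.0) == pytest.approx(2.5)
        assert threshold_from_maxima(2.0, 5.0, 0.0) == pytest.approx(5.0)
        assert threshold_from_maxima(2.0, 5.0, 1e6) == pytest.approx(2.0, abs=1e-4)

    def test_bimodal_threshold_between_modes(self):
        rng = np.random.default_rng(1)
        values = np.concatenate(
            [rng.normal(0.1, 0.01, 400), rng.normal(1.0, 0.05, 100)]
        )
        res = adaptive_threshold(values, weight=5.0)
        assert not res.fallback
        assert 0.1 < res.value < 1.0
        assert res.m1 < res.m2
        # W -> 0 gives the far mode, W -> inf approaches the near mode
        hi = adaptive_threshold(values, weight=0.0)
        lo = adaptive_threshold(values, weight=1e6)
        assert hi.value == pytest.approx(res.m2)
        assert lo.value == pytest.approx(res.m1, rel=0.05)

    def test_high_bias_mirrors_low_bias(self):
        rng = np.random.default_rng(2)
        values = np.concatenate(
            [rng.normal(0.1, 0.01, 400), rng.normal(1.0, 0.05, 100)]
        )
        lo = adaptive_threshold(values, weight=5.0, bias="low")
        hi = adaptive_threshold(values, weight=5.0, bias="high")
        assert lo.value < hi.value
        assert hi.value == pytest.approx((lo.m1 + 5 * lo.m2) / 6)

    def test_unimodal_falls_back_flagged(self):
        rng = np.random.default_rng(3)
        values = rng.normal(1.0, 0.01, 500)
        res = adaptive_threshold(values)
        if res.fallback:
            assert res.value == pytest.approx(values.mean() + 0.5 * values.std())


class TestMergeAndDetect:
    def test_gap_below_merge_distance_fuses(self):
        iv = [SegmentInterval(0, 100), SegmentInterval(150, 250)]
        gap = int(0.05 * RATE)  # 125 samples; gap here is 50 < 125
        merged = merge_intervals(iv, gap)
        assert len(merged) == 1 and merged[0].start == 0 and merged[0].end == 250

    def test_gap_exactly_merge_distance_not_merged(self):
        gap = int(0.05 * RATE)
        iv = [SegmentInterval(0, 100), SegmentInterval(100 + gap, 300 + gap)]
        assert len(merge_intervals(iv, gap)) == 2

    def test_merge_idempotent_and_gaps_respect_distance(self):
        rng = np.random.default_rng(4)
        starts = np.cumsum(rng.integers(30, 400, 40))
        iv = [SegmentInterval(int(s), int(s) + 25) for s in starts]
        gap = 125
        once = merge_intervals(iv, gap)
        twice = merge_intervals(once, gap)
        assert once == twice
        for a, b in zip(once, once[1:]):
            assert b.start - a.end >= gap

    def test_detect_components_empty_when_nothing_passes(self):
        env = EnvelopeSequence(
            np.full(10, 0.1), np.full(10, 50.0), 250, 250, RATE
        )
        th = ThresholdPair(
            energy=ThresholdResult(1.0), spread=ThresholdResult(10.0)
        )
        assert detect_components(env, th) == []

    def test_detect_components_finds_true_bursts(self, normal_record):
        from pcgpah.segmentation import estimate_thresholds

        rec, truth = normal_record
        env = compute_envelopes(rec)
        comps = detect_components(env, estimate_thresholds(env), record=rec)
        # every component overlaps a true S1 or S2 burst
        bursts = [
            (iv.start, iv.end)
            for c in truth.cycles
            for iv in (c.s1, c.s2)
        ]
        for comp in comps:
            assert any(comp.start < e and comp.end > s for s, e in bursts)


class TestLabeling:
    @staticmethod
    def _components(pattern_s, rate=RATE):
        """Build components from alternating (burst, gap) durations."""
        comps, t = [], 0
        for burst, gap in pattern_s:
            comps.append(
                SegmentInterval(int(t * rate), int((t + burst) * rate))
            )
            t += burst + gap
        return comps, int(t * rate)

    def test_max_gap_anchors_s2_s1_and_alternation(self):
        pattern = [(0.1, 0.20), (0.1, 0.45), (0.1, 0.21), (0.1, 0.44),
                   (0.1, 0.20), (0.1, 0.45), (0.1, 0.0)]
        comps, n = self._components(pattern)
        cycles = label_components(comps, n)
        assert len(cycles) == 3
        for c in cycles:
            assert c.s1.label == "S1" and c.s2.label == "S2"
            # systole shorter than diastole in every cycle
            assert c.systole.n_samples < c.diastole.n_samples

    def test_spurious_component_drops_only_its_cycle(self):
        # cycle 2 has an extra component splitting its systole
        pattern = [(0.1, 0.2), (0.1, 0.45),
                   (0.1, 0.05), (0.05, 0.05), (0.1, 0.45),
                   (0.1, 0.2), (0.1, 0.45), (0.1, 0.0)]
        comps, n = self._components(pattern)
        cycles = label_components(comps, n)
        starts = [c.start for c in cycles]
        assert comps[0].start in starts  # first cycle retained
        assert comps[5].start in starts  # third cycle retained
        assert comps[2].start not in starts  # broken cycle dropped

    def test_too_few_components_unsegmentable(self):
        comps = [SegmentInterval(0, 100), SegmentInterval(500, 600)]
        with pytest.raises(UnsegmentableRecord):
            label_components(comps, 1000)

    def test_uniform_gaps_unsegmentable(self):
        comps, n = self._components([(0.1, 0.3)] * 6)
        with pytest.raises(UnsegmentableRecord):
            label_components(comps, n)


class TestEndToEnd:
    def test_extract_cycles_slices(self, normal_record):
        rec, _ = normal_record
        ann = CycleAnnotation(
            s1=SegmentInterval(1000, 1300, "S1"),
            systole=SegmentInterval(1300, 2100, "systole"),
            s2=SegmentInterval(2100, 2350, "S2"),
            diastole=SegmentInterval(2350, 3000, "diastole"),
        )
        [(cycle, s2, _)] = extract_cycles(rec, [ann])
        assert cycle.size == 2000 and s2.size == 250

    def test_cycle_count_matches_heart_rate(self):
        spec = spec_for_class("Normal", seed=5, heart_rate_bpm=75.0)
        rec, truth = generate_record(spec)
        anns = segment_record(rec.normalized())
        assert 23 <= len(truth.cycles) <= 25
        assert len(anns) >= 0.85 * len(truth.cycles)

    def test_labels_strictly_alternate(self, pah_record):
        rec, _ = pah_record
        anns = segment_record(rec)
        assert len(anns) >= 4
        seq = sorted(
            [(a.s1.start, "S1") for a in anns]
            + [(a.s2.start, "S2") for a in anns]
        )
        labels = [lab for _, lab in seq]
        for a, b in zip(labels, labels[1:]):
            assert a != b
        for a in anns:
            assert a.s1.end == a.systole.start
            assert a.systole.end == a.s2.start
            assert a.s2.end == a.diastole.start
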