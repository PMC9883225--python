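# Methods

This note documents the models and procedures implemented in
`pcgpah`, the assumptions behind them, the parameters that matter, and
the choices made where the design was genuinely open. Nothing here
states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Signal model and working rate

Heart sounds are quasi-periodic: each cardiac cycle contains a first
heart sound (S1, closure of the mitral/tricuspid valves), a systolic
interval, a second heart sound (S2, closure of the aortic and pulmonic
valves) and a diastolic interval. Diagnostic content sits below 1 kHz,
so the pipeline operates at 2500 Hz; higher-rate recordings are
decimated with a polyphase FIR anti-aliasing filter (for the common
5000 Hz capture this is an exact rational factor of 1/2). Records are
amplitude-normalized to unit peak by default (configurable off) so
that detection thresholds are comparable across recording gains.

In CHD-PAH, elevated pulmonary pressure makes P2 (the pulmonic
component of S2) louder and later: S2 gains energy relative to the
cycle and splits audibly. The pipeline's feature set is built around
that signature.

## Segmentation

**Envelopes.** Non-overlapping 0.1 s frames (250 samples). Per frame:
short-time energy `E_i = (1/N) Σ |x_i(n)|²` on the raw (rectangular)
frame, and spectral spread `S_i` — the standard deviation (Hz) of the
Hamming-windowed frame's *power* spectrum about its centroid. Power
weighting is deliberate: with magnitude weighting the broadband noise
floor contributes mass proportional to the number of bins and swamps a
narrowband transient, and the envelope then carries no S1/S2-vs-noise
contrast at all; with power weighting a transient that dominates frame
energy also dominates the spectral mass, giving heart-sound frames a
distinctly small spread. An all-zero frame has spread 0 by convention.

**Adaptive thresholds.** Each envelope's histogram (50 bins, smoothed
with a 3-bin running mean whose window shrinks at the edges — zero
padding would displace a mode sitting against the histogram boundary)
is scanned for local maxima; the two *tallest* are the mode positions
`M1 < M2`. A threshold is the weighted mean of the two, and the weight
`W` (default 5) always biases the threshold toward the mode whose
frames the criterion *rejects*, which is what makes `W` a sensitivity
knob in both uses:

- energy criterion `E ≥ T_E`: `T_E = (W·M1 + M2)/(W+1)`, hugging the
  quiet mode;
- spread criterion `S ≤ T_S` (default direction, see below):
  `T_S = (M1 + W·M2)/(W+1)`, hugging the broadband-noise mode.

If the smoothed histogram exposes fewer than two maxima the threshold
falls back to `mean + 0.5·std`, flagged in the result.

**Spread direction.** Heart-sound components are narrowband and
low-frequency; broadband noise frames have large spread. The criterion
that selects components is therefore `S ≤ T_S` (`spread_direction =
"below"`). The opposite direction is implemented and configurable, but
selecting high-spread frames empirically intersects the energy
criterion almost nowhere on plausible records and defeats detection.

**Components.** Frames passing both criteria form candidate runs; runs
separated by strictly less than 50 ms merge (a gap of exactly 50 ms
does not). Because the coarse frame grid (0.1 s) is coarser than S2
itself, edges are then refined at 10 ms resolution: within each
component's neighbourhood, every fine-grained run above 25 % of the
energy threshold whose own peak clears the full threshold is kept as a
component (a single coarse run can legitimately contain both S1 and
S2, bridged by a soft murmur). The relaxed edge threshold matters
because a 10 ms window at a transient's onset holds far less energy
than a 0.1 s window centred on it; 25 % places the detected onset
within ~10 ms of the true burst onset while staying an order of
magnitude above the noise floor. Refined intervals re-merge under the
50 ms rule.

**Labeling.** Gaps between adjacent components are clustered into two
groups by a deterministic two-means on their durations: short gaps are
systoles, long gaps diastoles (the longest gap is always a diastole —
the rule that anchors S2 on its start side and S1 on its end side).
A cycle is emitted for every component pair matching the pattern
S1 → short gap → S2 → long gap → next S1 with a duration inside
0.4–1.5 s. Components breaking the pattern (spurious detections,
missed bursts) drop only the cycles they touch. Records with fewer
than four components, or whose gaps do not separate into two groups,
raise `UnsegmentableRecord` — an explicit outcome, never a silent
guess. Coordinates are 0-based sample indices in half-open intervals;
seconds = samples / 2500.

## Time-domain features

Per cycle and its S2: intensity `I = Σ x(i)²` (no 1/n — segment length
is itself informative and appears separately), the S2/cycle intensity
and duration ratios, and envelope peak pairs. Peaks are computed on
the rectified waveform smoothed with a 10 ms moving average, with a
20 ms minimum separation, so that the "second maximum" is a distinct
morphological event (A2 vs P2) rather than a neighbouring sample of
the same oscillation. The phase difference between the two largest S2
peaks tracks the A2–P2 split; the same pair is computed on the whole
cycle (configurable out of the final vector). When no second peak
satisfies the separation, the value pair (0, 0) is returned flagged.

## Frequency-domain features

Spectral entropy (bits), frequency center (Hz) and peak frequency (Hz)
are computed on fixed-length zero-padded DFTs — 256 points for the
cycle, 512 for S2 (the DC bin plus the positive half-spectrum is
kept). Zero padding refines bin spacing; segments longer than the DFT
length are truncated for these three summaries only. Pitch-like
statistics run framewise (0.05 s frames, 50 % overlap) over the *whole*
segment, reconciling the fixed DFT sizes with whole-signal statistics:

- fundamental frequency per frame by normalized autocorrelation,
  search band 20–400 Hz, voicing threshold 0.3 on the autocorrelation
  peak (which must be a local maximum — a plain argmax would pick the
  short-lag shoulder of the lag-0 peak), parabolic lag interpolation;
  mean/min/max over voiced frames;
- dominant frequencies: per-frame Hamming periodogram peaks above 5 %
  of the frame maximum, pooled and deduplicated at bin resolution;
  mean/min/max/range of the unique set.

Both estimators return zeros, flagged, when no frame yields an
estimate. Spectral skewness/kurtosis exist behind a config flag
(default off) and are not part of the canonical vector.

## PNCC feature images

Each cycle maps to a fixed `n_frames_out × L` image (64 × 40 default):

1. pre-emphasis `y[n] = x[n] − 0.95·x[n−1]`;
2. adaptive STFT: hop = ⌊n/(F+1)⌋, frame = 2·hop (50 % overlap), so any
   cycle tiles exactly F Hamming-windowed frames; frame length scales
   with cycle length;
3. gammatone filterbank, 40 channels on an ERB-rate scale over
   25–1000 Hz (the band cap matches the heart-sound content limit),
   each channel's squared response renormalized to sum exactly 1 on
   the DFT grid, so a white spectrum yields unit power in every
   channel;
4. medium-time power: running mean over ±2 frames, edge windows
   shrinking rather than zero-padding (zero padding would darken edge
   frames);
5. asymmetric noise suppression: a first-order tracker per channel
   (slow λ_a = 0.999 when rising, fast λ_b = 0.5 when falling,
   initialized at 0.9 of the first frame) estimates the noise floor;
   the floor is subtracted and half-wave rectified; a second tracker
   of the rectified signal provides the re-insertion level for
   non-excitation frames (frames below 2× that floor); temporal
   masking (decay 0.85, attenuation 0.2) suppresses trailing echoes;
6. frequency smoothing: the suppression transfer ratio R/Q is averaged
   over ±4 channels (channels with Q below 10⁻¹²·max(Q) contribute
   ratio 0) and applied to the raw power P;
7. mean-power normalization `U = k·T/μ[m]` with
   `μ[m] = λ_μ·μ[m−1] + ((1−λ_μ)/L)·Σ_l T[m,l]`, λ_μ = 0.999, then
   `V = U^(1/15)`.

μ[0] is initialized from the first frame's channel mean: cycles are
~10²–10³ frames shorter than λ_μ's time constant, so a zero start
would leave the whole image inside a startup transient. All stages are
homogeneous in signal power and all thresholds are relative, so the
image is gain-invariant to float precision — verified at ×0.1/×10 in
the acceptance suite. The constants of stages 5–7 follow the published
power-normalized-cepstral lineage and are all configurable. The V
matrix itself is the image (no DCT); a DCT export to conventional
cepstral coefficients exists but is off by default.

## Deep-feature extractor

A compact CNN: three 3×3 convolution blocks (16/32/64 filters, ReLU,
2×2 max pooling), dropout 0.5, a 64-unit fully connected layer (the
feature layer), and a 3-class softmax head used only to supervise
training (cross-entropy, Adam at η = 0.001, β₁ = 0.9, β₂ = 0.999,
batch 32). Images are standardized by the training set's global
mean/std, stored for inference. The network is implemented directly on
numpy (im2col convolutions, explicit backward passes): at this scale
that is fast on one CPU and bitwise reproducible for a given seed,
which the pipeline's reproducibility contract relies on. Extraction
runs with dropout off and returns the 64 penultimate activations.

Training-epoch choice: on a ~300-image corpus the loss converges on
class-structured labels within about three epochs, while the network —
whose FC layer alone has ~164k parameters — begins to memorize
*shuffled* labels from roughly five epochs on. Short training is
therefore the regularizer of choice at this corpus scale; the test
suite's shuffled-label control (training accuracy ≈ chance) runs at
three epochs for exactly this reason. The default epoch budget in
`CnnSpec` is 50 for larger corpora, where memorization pressure per
epoch is far lower.

## Fusion, selection, classification, voting

Per-cycle fusion vector: 12 time-domain + 20 frequency-domain columns,
plus the 64 deep columns when the CNN path is enabled. Selection is
fitted on the training split only and replayed frozen at inference:

1. variance filter: columns with population variance < 0.05 are
   dropped (strictly below; a column at exactly 0.05 survives). The
   deep block bypasses this filter — an absolute variance threshold is
   meaningless on the compressed scale of network activations, and the
   fused vector is defined to carry the full 64-dimensional learned
   representation;
2. importance ranking: an auxiliary XGBoost model (same
   hyperparameters) ranks surviving columns by total gain; the top
   `target_dim − 64` time/frequency columns are kept plus the intact
   deep block. Ties and never-used columns rank by original order, so
   the mask is deterministic. `target_dim` defaults to
   min(212, available): the canonical 212 = 148 + 64 composition is
   enforced whenever enough features exist. The enumerable
   time/frequency set here (32 per cycle) is far smaller than 212, so
   on this pipeline the filter is the only reduction; the 212 target
   matters when users extend the vector (e.g. framewise statistics).

The cycle classifier is XGBoost with 600 trees, depth 7, min child
weight 1, L1 = 1, L2 = 3, learning rate 0.01, `multi:softprob`,
single-threaded and seeded for determinism.

Records are labeled by majority vote over their cycle labels: the
single-pass Boyer–Moore candidate (guaranteed correct when a strict
majority exists) is verified by a counting pass; without a strict
majority the maximal-count class wins, ties broken by the fixed class
order Normal < CHD < CHD-PAH. Unsegmentable records return an
explicit undetermined prediction. Splitting is stratified *by record*
(60/20/20 train/val/test, seeded): cycles of one record are
near-duplicates, and splitting by cycle would leak held-out
information.

## Synthetic phonocardiograms

The simulator generates what the method assumes, with exact
ground-truth annotations:

- cycles of 0.6–1.0 s (heart rate drawn 60–100 bpm per record, ±3 %
  per-cycle jitter), systole a fixed 35 % of the cycle;
- S1: Gaussian-enveloped downward chirp, 45 Hz center, 120 ms, unit
  amplitude; S2: 70 Hz, 100 ms, amplitude 0.8 before class scaling.
  The Gaussian σ is 1/5 of the burst duration, so the annotated
  support edge is acoustically meaningful (envelope ~4 % of peak)
  rather than a mathematical tail;
- class morphology: Normal — single S2 lobe; CHD — 15 ms A2–P2 split
  (P2 at 0.7 relative amplitude), S2 ×1.15, systolic murmur
  (150–400 Hz band-passed noise) at 0.05 relative amplitude; CHD-PAH —
  40 ms split, P2 0.8, S2 ×1.6, murmur 0.04. Murmur levels are set
  subordinate to the primary sounds, as in mild-to-moderate disease:
  a murmur whose frame energy rivals S1/S2 defeats *any* frame-level
  energy detector, including this one (a known limitation of the
  double-threshold method, not of the simulator);
- additive broadband noise low-passed below 1 kHz at a configurable
  SNR (default 15 dB; the segmentation-recovery acceptance runs at
  20 dB), so records respect the band-limit premise of the 2500 Hz
  working rate.

Everything derives from a single integer seed. What passing tests on
this simulator shows: the segmenter recovers onsets it was designed to
find, features order classes the way auscultation says they should,
and the pipeline's plumbing (selection replay, voting, determinism) is
correct. What it does not show: performance on real stethoscope
recordings, with respiration-modulated splitting, variable murmur
grades, sensor artifacts and inter-patient variability.

## Numerical conventions and degenerate inputs

- Intervals are half-open `[start, end)` in 0-based samples.
- All-zero frames: energy 0, spread 0; all-zero spectra: entropy,
  center, peak all 0, flagged.
- Estimator failures (no second peak, no voiced frame, no PSD peak)
  return flagged sentinels (zeros) rather than NaN; cycles whose
  contracts cannot be met (e.g. an S2 shorter than twice the peak
  separation) are skipped during featurization, not poisoned.
- The merge comparison is strict (< 50 ms merges); the variance
  threshold is strict (< 0.05 drops); gap two-means and importance
  ties resolve deterministically.
- WAV I/O uses symmetric 16-bit scaling (÷32767 on read, ×32767 on
  write) so a write/read round trip is within one quantization step.

## Problem sizes

Default test-suite and acceptance scales, chosen as the package's
standard desk-scale conditions: 50 records (≈2500 onsets) for
segmentation recovery; 10 cycles × 2 gains for PNCC invariance; 1000
sequences for the voting oracle; ~300 images × 3 epochs for the
deep-feature contract; 99 records (≈2400 cycles, 60/20/20 split) for
the end-to-end run with the time/frequency path (the deep path is
exercised separately at reduced scale — its contribution to held-out
accuracy on this simulator is nil because the time/frequency features
already separate the classes).
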