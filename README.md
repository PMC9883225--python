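# pcgpah

Non-invasive screening of pulmonary arterial hypertension associated
with congenital heart disease (CHD-PAH) from heart-sound recordings
(phonocardiograms, PCG).

CHD-PAH is a severe complication of congenital heart disease whose
definitive diagnosis requires right-heart catheterization. Its
auscultatory hallmark, however, is audible: a loud second heart sound
(S2) with a widened split between its aortic (A2) and pulmonic (P2)
components. This package implements a complete machine pipeline that
exploits that signature — for biomedical-signal researchers and
engineers building stethoscope-based screening tools:

1. **Segmentation.** The record (resampled to 2500 Hz) is framed into
   non-overlapping 0.1 s windows; per frame the short-time energy
   `E_i = (1/N) Σ_n |x_i(n)|²` and the spectral spread `S_i` (std of the
   frame spectrum about its centroid, Hz) are computed. Each envelope's
   histogram is bimodal — quiet systole/diastole frames vs. loud S1/S2
   frames — and a threshold `T = (W·M1 + M2)/(W + 1)` is placed between
   the two tallest histogram modes `M1 < M2`. Frames loud in energy and
   narrowband in spread are heart-sound components; runs closer than
   50 ms merge, and components become S1/S2 via the physiological rule
   that diastole is the longest inter-component interval.
2. **Time/frequency features** per cardiac cycle and per S2: intensities
   `I_k = Σ_i x_k(i)²` and their ratio, durations and their ratio,
   envelope peak pairs and their phase difference (the A2–P2 split
   surrogate), spectral entropy, frequency center, peak frequency,
   fundamental-frequency and dominant-frequency statistics on 256-pt
   (cycle) / 512-pt (S2) zero-padded DFTs and framewise periodograms.
3. **PNCC feature images.** Each cycle is mapped to a fixed 64 × 40
   power-normalized image: pre-emphasis (k = 0.95), an adaptive STFT
   with cycle-length-dependent frames, a unit-power gammatone
   filterbank, medium-time power (±2 frames), asymmetric noise-floor
   subtraction with temporal masking, frequency smoothing, running
   mean-power normalization and a 1/15 power law. The image is
   invariant to recording gain by construction.
4. **Deep features.** A small CNN (3 conv + 3 pool blocks, dropout,
   FC-64, softmax head; Adam with η = 0.001, β₁ = 0.9, β₂ = 0.999)
   trains on labeled PNCC images; the 64 penultimate activations are
   the deep features. The class head is discarded after training.
5. **Fusion, classification, voting.** Time/frequency and deep features
   fuse into one vector; a variance filter (< 0.05 dropped) and
   boosted-tree importance ranking select the final vector (target
   212 = 148 + 64, deep block never removed). An XGBoost three-class
   model (600 trees, depth 7, min child weight 1, L1 = 1, L2 = 3,
   learning rate 0.01) labels each cycle; the record label is the
   Boyer–Moore majority vote over its 20–33 cycles, verified by a
   counting pass.

Clinical CHD-PAH recordings cannot be redistributed, so the package
ships a synthetic-PCG simulator (`pcgpah.synthetic_pcg`) that generates
labeled records with exact ground-truth S1/systole/S2/diastole
annotations and class-dependent S2 morphology (Normal: single S2;
CHD: 15 ms split + soft systolic murmur; CHD-PAH: 40 ms split, S2
×1.6 louder). Every stage is tested against it.

## Worked example

```bash
python examples/train_and_evaluate.py
```

```
corpus: 99 records, {'Normal': 33, 'CHD': 33, 'CHD-PAH': 33}
val: cycle accuracy 0.994, record accuracy 1.000 (21 records)
test: cycle accuracy 1.000, record accuracy 1.000 (18 records)
test confusion matrix (rows = true, cols = predicted):
         Normal  CHD  CHD-PAH
Normal        6    0        0
CHD           0    6        0
CHD-PAH       0    0        6
```

99 synthetic records are split by record (never by cycle) 60/20/20
into train/validation/test; the pipeline trains on cycle-level fusion
vectors and votes per record. Record accuracy ≥ cycle accuracy shows
the point of the vote: isolated cycle errors are outvoted by the
~20–30 cycles of the same record. `examples/` holds three further
scripts — segmentation against ground truth, feature extraction per
class, and PNCC image computation with a gain-invariance check.

The same pipeline is scriptable from the shell:

```bash
pcgpah simulate --n 20 --seed 7 --out data/
pcgpah train data/manifest.csv --out model/
pcgpah predict model/ data/normal-000.wav
pcgpah evaluate model/ data/manifest.csv --confusion confusion.csv
```

## Limitations

The simulator emulates the signal properties the method assumes —
quasi-periodic cycles, S2-concentrated pathology, content below
1 kHz — not hemodynamics. Accuracy on it demonstrates algorithmic
correctness, not clinical performance; see `docs/methods.md` for the
full model description, parameter rationale and known limitations.
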