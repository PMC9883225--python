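"""Compute PNCC feature images and demonstrate their gain invariance.

The power-normalized chain maps every cardiac cycle — whatever its
length — onto a fixed 64 x 40 non-negative image whose values do not
depend on the recording gain, which is what makes it a stable CNN
input across stethoscopes and patients.
"""

import numpy as np

from pcgpah.pncc import pncc_image
from pcgpah.synthetic_pcg import generate_record, spec_for_class

rec, truth = generate_record(spec_for_class("Normal", seed=8))
rec = rec.normalized()

for k, ann in enumerate(truth.cycles[:3]):
    cycle = rec.samples[ann.start : ann.end]
    img = pncc_image(cycle)
    scaled = pncc_image(10.0 * cycle)
    dev = np.max(np.abs(scaled.values - img.values))
    print(
        f"cycle {k}: {cycle.size} samples -> image {img.values.shape}, "
        f"value range [{img.values.min():.3f}, {img.values.max():.3f}], "
        f"gain x10 deviation {dev:.2e}"
    )
# All three cycles, despite different lengths, give 64 x 40 images, and
# multiplying the waveform by 10 changes the image by ~1e-15 (float
# noise): the mean-power normalization cancels gain exactly.
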