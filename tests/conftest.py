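"""Shared fixtures: small synthetic records and cycle inventories."""

from __future__ import annotations

import numpy as np
import pytest

from pcgpah.pncc import pncc_image
from pcgpah.synthetic_pcg import generate_record, spec_for_class

RATE = 2500


@pytest.fixture(scope="session")
def normal_record():
    rec, truth = generate_record(spec_for_class("Normal", seed=2))
    return rec.normalized(), truth


@pytest.fixture(scope="session")
def pah_record():
    rec, truth = generate_record(spec_for_class("CHD-PAH", seed=2))
    return rec.normalized(), truth


@pytest.fixture(scope="session")
def true_cycles(normal_record):
    """Waveforms of the first ten ground-truth cycles of a normal record."""
    rec, truth = normal_record
    return [rec.samples[c.start : c.end] for c in truth.cycles[:10]]


@pytest.fixture(scope="session")
def labeled_images():
    """~300 PNCC images with class labels (100 per class)."""
    images, labels = [], []
    for label in ("Normal", "CHD", "CHD-PAH"):
        got = 0
        for seed in range(6):
            rec, truth = generate_record(spec_for_class(label, seed=seed))
            rec = rec.normalized()
            for c in truth.cycles:
                if got >= 100:
                    break
                images.append(pncc_image(rec.samples[c.start : c.end]))
                labels.append(label)
                got += 1
    return images, labels
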