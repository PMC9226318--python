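"""Shared fixtures: rendered eyes, small cohorts and scorer outputs.

Everything is generated programmatically at test time from fixed seeds; no
image fixtures are stored on disk.
"""

from dataclasses import replace

import numpy as np
import pytest

from taoscope.signs import score_sign
from taoscope.synthetic import EyePhenotype, gaze, render_eye, sample_patient


@pytest.fixture(scope="session")
def default_phenotype():
    return EyePhenotype.default(160)


@pytest.fixture(scope="session")
def default_eye(default_phenotype):
    """A primary-gaze rendered eye tile with mild noise."""
    return render_eye(default_phenotype, gaze("primary"), 160, seed=0)


@pytest.fixture(scope="session")
def congestion_scores():
    """Conjunctival-congestion scores on 200 rendered crops, redness
    sampled by label — a seeded recovery experiment reused by the scorer
    and bootstrap-CI tests."""
    rng = np.random.default_rng(2024)
    base = EyePhenotype.default(160)
    scores, labels = [], []
    for i in range(200):
        label = i % 2
        redness = float(rng.uniform(0.55, 0.90)) if label else float(rng.uniform(0.0, 0.20))
        phen = replace(base, redness=redness)
        eye = render_eye(phen, gaze("primary"), 160, seed=int(rng.integers(2**31)))
        s = score_sign(eye.image, eye.segmentation, "conjunctival_congestion")
        scores.append(s.probability)
        labels.append(label)
    return np.array(scores), np.array(labels)
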