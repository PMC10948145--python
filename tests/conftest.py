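"""Shared fixtures.

The expensive fixtures (a trained classifier and a full-movie detection
run) are session-scoped so the classifier-sanity and end-to-end tests
share one training run.
"""

import numpy as np
import pytest

from apodetect.pipeline import PipelineConfig, detect
from apodetect.synth import SynthConfig, generate
from apodetect.tracking import track
from apodetect.workflow import train_synthetic_classifier

TRAIN_SEED = 11


@pytest.fixture(scope="session")
def trained_classifier():
    """Desk-scale classifier trained on 500 clips/class for 20 epochs,
    plus a held-out test split that never entered training."""
    clf, (X_test, y_test) = train_synthetic_classifier(seed=TRAIN_SEED)
    return {"clf": clf, "X_test": X_test, "y_test": y_test}


@pytest.fixture(scope="session")
def detection_run(trained_classifier):
    """Full-pipeline run with default deployment parameters on a seeded
    movie with ~100 near-confluent nuclei and 30 planted events."""
    cfg = SynthConfig(H=256, W=256, T=100, n_cells=100, n_apoptoses=30,
                      noise_sd=4.0, seed=77)
    sm = generate(cfg)
    detections = detect(sm.movie, trained_classifier["clf"], PipelineConfig())
    tracks = track(detections)
    return {"movie": sm, "detections": detections, "tracks": tracks}


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
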