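import numpy as np
import pytest

import gaitdtw as g


@pytest.fixture(scope="session")
def sim_a():
    """Default 10-min mixed schedule, seed 1 — template-building recording."""
    cfg = g.SimulationConfig(seed=1)
    rec, labels, bounds = g.generate_recording(cfg)
    return cfg, rec, labels, bounds


@pytest.fixture(scope="session")
def trained(sim_a):
    """Templates + calibrated thresholds built from the seed-1 recording."""
    _, rec, labels, bounds = sim_a
    snippets = g.extract_snippets(rec, labels, bounds)
    templates = g.build_template_set(snippets)
    thresholds = g.calibrate_thresholds(templates, snippets)
    return templates, thresholds, snippets


@pytest.fixture(scope="session")
def recognized_b(trained):
    """Frame scores of the seed-2 recording under the seed-1 templates."""
    templates, thresholds, _ = trained
    cfg = g.SimulationConfig(seed=2)
    rec, labels, _ = g.generate_recording(cfg)
    scores = g.recognize(rec, templates, g.RecognitionConfig(thresholds=thresholds))
    return scores, labels


@pytest.fixture()
def zeros_recording():
    return g.ImuRecording(np.zeros((50, 6)))
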