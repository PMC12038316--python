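"""Shared fixtures: stimuli, models and trained networks.

The trained models are session-scoped because training (seconds) and
receptive-field mapping (minutes) are the expensive steps shared by the
end-to-end tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import scenenet as sn

GLYPH_SEED = 0
NATURAL_SEED = 0

# the natural-scene demonstration configuration: higher sparseness targets
# (0.3 / 0.4 / 0.4) and no lateral inhibition
NATURAL_OVERRIDES = {
    "architecture": {
        "layer1": {"sparseness": 0.3, "lateral_inhibition": {"enabled": False}},
        "layer2": {"sparseness": 0.4, "lateral_inhibition": {"enabled": False}},
        "layer3": {"sparseness": 0.4, "lateral_inhibition": {"enabled": False}},
    }
}


@pytest.fixture(scope="session")
def gabor_bank():
    return sn.build_gabor_bank()


@pytest.fixture(scope="session")
def glyph_scene():
    return sn.SceneSpec(
        {"UL": sn.digits_patch(), "UR": sn.letters_patch()}, name="glyphs"
    )


@pytest.fixture(scope="session")
def natural_patches():
    return sn.make_natural_like(11), sn.make_natural_like(12)


@pytest.fixture(scope="session")
def glyph_model(glyph_scene):
    """Model trained for 7 epochs on the two alphanumeric fixation patches
    (digits at gaze UL, letters at gaze UR) with the default architecture."""
    model = sn.build_model(sn.make_config({"seed": GLYPH_SEED}))
    sn.train(model, glyph_scene)
    return model


@pytest.fixture(scope="session")
def natural_model(natural_patches):
    """Model trained on two natural-like fixation patches (UL, UR) with the
    natural-scene demonstration configuration."""
    p3, p4 = natural_patches
    cfg = sn.make_config({"seed": NATURAL_SEED, **NATURAL_OVERRIDES})
    model = sn.build_model(cfg)
    sn.train(model, sn.SceneSpec({"UL": p3, "UR": p4}, name="natural"))
    return model


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
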