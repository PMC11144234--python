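"""Shared fixtures: synthetic study scenes and the trained models on them.

Expensive artifacts (the GAN smoke training, the fitted stacking ensemble,
the change-detection run) are session-scoped so unit and end-to-end tests
share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from postfire import change as change_mod
from postfire import gan as gan_mod
from postfire import regrowth as regrowth_mod
from postfire import synth


@pytest.fixture(scope="session")
def burn_scene():
    """Seeded bi-temporal burn scene with its ground-truth scar mask."""
    return synth.make_burn_pair(synth.SceneConfig(seed=1))


@pytest.fixture(scope="session")
def change_result(burn_scene):
    pre, post, truth = burn_scene
    cm = change_mod.detect_change(pre, post)
    return cm, truth


@pytest.fixture(scope="session")
def trend_stack():
    return synth.make_trend_stack(synth.TrendStackConfig(seed=7))


@pytest.fixture(scope="session")
def soil_data():
    return synth.make_soil_table(n=2000, noise_rate=0.05, seed=5)


@pytest.fixture(scope="session")
def stack_fit(soil_data):
    table, _ = soil_data
    return regrowth_mod.fit_stack(table, regrowth_mod.StackConfig(seed=5),
                                  evaluate_bases=True)


@pytest.fixture(scope="session")
def blob_features():
    """Three well-separated Gaussian blobs in 6-D, rescaled to [0, 1]."""
    rng = np.random.default_rng(0)
    centers = np.array([[0, 0, 0, 0, 0, 0],
                        [5, 5, 0, 0, 0, 0],
                        [0, 0, 5, 5, 0, 0]], float)
    x = np.vstack([c + 0.3 * rng.standard_normal((300, 6)) for c in centers])
    labels = np.repeat([0, 1, 2], 300)
    x = (x - x.min()) / (x.max() - x.min())
    return x, labels


@pytest.fixture(scope="session")
def dec_blobs(blob_features):
    x, labels = blob_features
    cfg = change_mod.DECConfig(
        ae=change_mod.SparseAEConfig(layer_widths=(16, 4), epochs=100, seed=0))
    return change_mod.train_dec(x, 3, cfg), labels


@pytest.fixture(scope="session")
def recovery_pairs():
    return synth.make_recovery_pairs(synth.RecoveryPairsConfig(n=200, seed=3))


@pytest.fixture(scope="session")
def gan_model(recovery_pairs):
    """Seeded smoke training: 200 synthetic 32x32 pairs, 30 epochs."""
    pairs, _ = recovery_pairs
    return gan_mod.train_adaptigan(pairs, gan_mod.GANConfig(seed=3, epochs=30))
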