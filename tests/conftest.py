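"""Shared fixtures: tiny networks and session-scoped trained ensembles."""

import numpy as np
import pytest

from sais.estimators import TemporalPrototypeClassifier
from sais.model import EncoderConfig, SAISNet
from sais.synthetic import SyntheticConfig, gen_dataset, gen_timeline
from sais.training import TrainConfig, cross_validate


@pytest.fixture
def tiny_net():
    """Small random network for forward-pass properties (no training)."""
    cfg = EncoderConfig(dim=8, embed_dim=6, n_layers=2, n_heads=2, max_t=32, dropout=0.0)
    return SAISNet(cfg, ["a", "b", "c"], np.random.default_rng(0))


@pytest.fixture(scope="session")
def gesture_study():
    """The synthetic gesture study: config, clips (with background), timeline."""
    cfg = SyntheticConfig(categories=("hook", "clip", "cold_cut"), dim=32,
                          snr=5.0, seed=11)
    clips = gen_dataset(160, cfg, task="gesture", include_background=True)
    app, flow, truth = gen_timeline(600.0, cfg)
    return {"config": cfg, "clips": clips, "appearance": app, "flow": flow, "truth": truth}


@pytest.fixture(scope="session")
def gesture_ensemble(gesture_study):
    """Ten-fold Monte Carlo ensemble trained on the synthetic gesture clips."""
    models, reports = cross_validate(
        gesture_study["clips"], n_folds=10,
        config=TrainConfig(n_epochs=15, seed=5),
        n_layers=2, n_heads=4, embed_dim=32,
    )
    return models, reports


@pytest.fixture(scope="session")
def small_trained_clf(gesture_study):
    """One quickly trained classifier (for explanation / checkpoint tests)."""
    clips = gesture_study["clips"][:48]
    clf = TemporalPrototypeClassifier(n_layers=2, n_heads=4, embed_dim=32,
                                      n_epochs=6, random_state=1)
    clf.fit(clips, [c.category for c in clips])
    return clf
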