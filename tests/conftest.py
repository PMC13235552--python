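"""Shared fixtures: generator presets and session-scoped trained models.

Training the desk-scale models (gradient-boosted ray classifier, SE-residual
ensemble, SSEM) takes a few seconds each, so they are built once per session
and reused across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

from mpspec.artifacts import build_ray_training_set, train_ray_classifier
from mpspec.classification import DRNConfig, train_ensemble
from mpspec.imaging import SSEMConfig, fit_ssem
from mpspec.ood import ClassStats
from mpspec.synth import (
    NONPOLYMER_PRESETS,
    RAMAN_PRESETS,
    FTIR_PRESETS,
    generate_canonical_class,
    generate_image,
    generate_library,
)

#: Small residual-network configuration used throughout the suite: two
#: blocks, aggressive pooling, three folds — trains in seconds while keeping
#: every architectural ingredient (multiscale kernels, SE gating, skips).
TOY_DRN = dict(
    n_classes=5,
    channels=(6, 12),
    kernels=(3, 7, 15),
    se_reduction=2,
    stem_stride=4,
    pool=4,
    epochs=20,
    batch_size=32,
    folds=3,
)


@pytest.fixture(scope="session")
def toy_drn_kwargs():
    return dict(TOY_DRN)


@pytest.fixture(scope="session")
def raman_specs():
    return list(RAMAN_PRESETS.values())


@pytest.fixture(scope="session")
def ftir_specs():
    return list(FTIR_PRESETS.values())


@pytest.fixture(scope="session")
def toy_dataset(raman_specs):
    """Separable 5-class training set: 60 clean canonical spectra per class."""
    x, y = [], []
    for i, spec in enumerate(raman_specs):
        for s in generate_canonical_class(spec, 60, 1000 + i):
            x.append(s.intensities)
            y.append(spec.label)
    return np.array(x), np.array(y)


@pytest.fixture(scope="session")
def toy_ensemble(toy_dataset):
    x, y = toy_dataset
    return train_ensemble(x, y, DRNConfig(**TOY_DRN), seed=0)


@pytest.fixture(scope="session")
def toy_class_stats(toy_ensemble, toy_dataset):
    x, y = toy_dataset
    return ClassStats.fit(toy_ensemble.embed(x), y)


@pytest.fixture(scope="session")
def ray_classifier(raman_specs):
    features, labels = build_ray_training_set(raman_specs, n_scenarios_per_class=4, seed=7)
    return train_ray_classifier(features, labels, model="gb", seed=0)


@pytest.fixture(scope="session")
def raman_library(raman_specs):
    return generate_library(raman_specs, 8, seed=11, clean=True)


@pytest.fixture(scope="session")
def nonpolymer_library():
    return generate_library(list(NONPOLYMER_PRESETS.values()), 5, seed=13, clean=True)


@pytest.fixture(scope="session")
def training_image():
    image, truth = generate_image(24, 24, substrate_fraction=0.8, seed=21)
    return image, truth


@pytest.fixture(scope="session")
def ssem_model(training_image):
    image, truth = training_image
    return fit_ssem([(image, truth)], SSEMConfig(cv_folds=5), seed=0)
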