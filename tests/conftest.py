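"""Shared fixtures: a desk-scale planted cohort, trained model, and sleep
assessment, all generated at test time (no stored data).

The study conditions are fixed once: 6 training subjects x 20 channels x
10 min at 128 Hz with 25% strong-contrast EpiNet channels; a held-out
40 min "sleep" subject with a 15 min ultradian cycle assessed with a
2 min window and 1 min step. Expensive artifacts are session-scoped so
the acceptance tests and unit tests share them.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from epinet.config import PipelineConfig
from epinet.pipeline import apply_model, fit_model
from epinet.features import sliding_window_features
from epinet.synth import CohortSpec, generate_cohort

TRAIN_SEED = 42
FIT_SEED = 1
SLEEP_SEED = 777

SLEEP_WINDOW_S = 120.0
SLEEP_STEP_S = 60.0


@pytest.fixture(scope="session")
def cfg() -> PipelineConfig:
    return PipelineConfig.reduced()


@pytest.fixture(scope="session")
def training_cohort():
    spec = CohortSpec(
        n_subjects=6, channels_per_subject=20, duration=600.0,
        sampling_rate=128.0, epinet_fraction=0.25, seed=TRAIN_SEED,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def trained(training_cohort, cfg):
    recs, _ = training_cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model, info = fit_model(recs, cfg, seed=FIT_SEED)
    return model, info


@pytest.fixture(scope="session")
def sleep_subject():
    spec = CohortSpec(
        n_subjects=1, channels_per_subject=20, duration=2400.0,
        sampling_rate=128.0, ultradian_period=15.0, epinet_fraction=0.25,
        seed=SLEEP_SEED,
    )
    recs, gt = generate_cohort(spec, mode="sleep")
    return recs[0], gt


@pytest.fixture(scope="session")
def sleep_features(sleep_subject, cfg):
    rec, _ = sleep_subject
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sliding_window_features(
            rec, cfg, window_s=SLEEP_WINDOW_S, step_s=SLEEP_STEP_S
        )


@pytest.fixture(scope="session")
def sleep_assessment(trained, sleep_subject, sleep_features, cfg):
    model, _ = trained
    rec, _ = sleep_subject
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return apply_model(
            model, rec, cfg, window_s=SLEEP_WINDOW_S, step_s=SLEEP_STEP_S,
            features=sleep_features,
        )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
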