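"""Shared fixtures: synthetic study data generated once per session.

The heavy end-to-end fixtures (full subject simulations and the
within-subject five-fold run) are session-scoped and lazy, so unit tests
never pay for them.  Study conditions (record length, number of records,
noise levels) are scaled-down versions of a drug-bolus protocol: ~40 s
records of ~70 beats each instead of multi-minute recordings.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from hemobeat.evaluation import make_folds_scheme1, prepare_beat_dataset, run_scheme
from hemobeat.synthetic import PROFILE_B, SyntheticConfig, simulate_subject

#: Study-condition constants used by the end-to-end tests.
RECORD_DURATION_S = 40.0
N_RECORDS_A = 8
N_RECORDS_B = 5
SUBJECT_A_SEED = 2024001
SUBJECT_B_SEED = 2024002
TRAIN_EPOCHS = 16
TRAIN_BATCH = 16


@pytest.fixture(scope="session")
def subject_a():
    """Eight bolus records (~70 beats each) for the primary subject."""
    config = SyntheticConfig(
        subject_id="subjA", duration_s=RECORD_DURATION_S, seed=SUBJECT_A_SEED
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        records, truth = simulate_subject(config, N_RECORDS_A)
    return records, truth


@pytest.fixture(scope="session")
def subject_b():
    """Six records for a second subject with shifted coupling profile."""
    config = SyntheticConfig(
        profile=PROFILE_B,
        subject_id="subjB",
        duration_s=RECORD_DURATION_S,
        seed=SUBJECT_B_SEED,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        records, truth = simulate_subject(config, N_RECORDS_B)
    return records, truth


@pytest.fixture(scope="session")
def dataset_a(subject_a):
    records, _ = subject_a
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return prepare_beat_dataset(records)


@pytest.fixture(scope="session")
def dataset_ab(subject_a, subject_b):
    records_a, _ = subject_a
    records_b, _ = subject_b
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return prepare_beat_dataset(records_a + records_b)


@pytest.fixture(scope="session")
def scheme1_result(dataset_a):
    """Five-fold within-subject evaluation of the primary subject."""
    plan = make_folds_scheme1(dataset_a.record_ids(), k=5, seed=SUBJECT_A_SEED)
    return run_scheme(
        dataset_a,
        plan,
        epochs=TRAIN_EPOCHS,
        batch_size=TRAIN_BATCH,
        seed=SUBJECT_A_SEED % 100000,
    )


@pytest.fixture(scope="session")
def cross_subject_results(dataset_ab):
    """Plain and calibrated cross-subject runs targeting the primary subject."""
    from hemobeat.evaluation import make_split_calibration, make_split_scheme2

    by_subject = dataset_ab.by_subject()
    kw = dict(epochs=TRAIN_EPOCHS, batch_size=TRAIN_BATCH, seed=SUBJECT_A_SEED % 100000)
    plain = run_scheme(
        dataset_ab, make_split_scheme2(by_subject, "subjA", seed=SUBJECT_A_SEED), **kw
    )
    calibrated = run_scheme(
        dataset_ab,
        make_split_calibration(by_subject, "subjA", n_cal=1, seed=SUBJECT_A_SEED),
        **kw,
    )
    return plain, calibrated


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
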