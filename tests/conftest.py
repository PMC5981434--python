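"""Shared fixtures: scaled-down synthetic recordings and feature factories.

Signal-level fixtures use short nights (~1.5 h sleep with 15 min wake
padding) so the full 64 Hz pipeline stays fast; class effects are
expressed in units of between-night SD, so discriminability does not
depend on night length to first order.
"""

import numpy as np
import pytest

from migrasleep import (NightFeatureVector, SleepDetectorParams,
                        SubjectProfile, segment_label_nights)
from migrasleep.features import N_FEATURES


SHORT_NIGHT = dict(
    sleep_duration_mean=1.5, sleep_duration_sd=0.1,
    sleep_onset_hour=23.5, sleep_onset_sd=0.1,
    wake_pad_hours=0.25, missing_night_prob=0.0,
)

#: detector params matched to the short fixtures (minimum 1 h sleep)
SHORT_PARAMS = SleepDetectorParams(min_sleep_s=3600.0)


def short_profile(**overrides) -> SubjectProfile:
    kwargs = dict(SHORT_NIGHT)
    kwargs.update(overrides)
    return SubjectProfile(**kwargs)


def make_feature_vector(rng, night_id, subject_id="S1", label="non_migraine",
                        shift=0.0, shift_dims=slice(0, 5)) -> NightFeatureVector:
    """A synthetic nightly vector: standard-normal features, optionally
    with the first few dimensions shifted for the pre-migraine class."""
    v = rng.normal(0.0, 1.0, N_FEATURES)
    if label == "pre_migraine" and np.any(shift):
        v[shift_dims] += shift
    return NightFeatureVector(night_id, subject_id, label, v)


def make_night_set(rng, n_mig, n_non, subject_id="S1", shift=0.0):
    vecs = [make_feature_vector(rng, f"{subject_id}_m{i:02d}", subject_id,
                                "pre_migraine", shift) for i in range(n_mig)]
    vecs += [make_feature_vector(rng, f"{subject_id}_n{i:02d}", subject_id,
                                 "non_migraine") for i in range(n_non)]
    return vecs


@pytest.fixture(scope="session")
def small_signal_nights():
    """Six short nights (2 pre-migraine) run through the full signal
    pipeline: generation, sleep detection, segmentation, labelling."""
    from migrasleep import DEFAULT_EFFECT, generate_subject_dataset

    profile = short_profile(subject_id="S1", n_days=6, n_migraine_days=2)
    sessions, diary = generate_subject_dataset(profile, DEFAULT_EFFECT, seed=7)
    nights = segment_label_nights(sessions, diary, SHORT_PARAMS)
    assert len(nights) == 6
    return nights
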