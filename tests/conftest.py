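import dataclasses

import pytest

import emgdose as e


@pytest.fixture(scope="session")
def small_config() -> e.CohortConfig:
    """A small but fully structured cohort: 3 subjects, 2 sessions, 2 s trials."""
    return e.CohortConfig(
        n_subjects=3,
        n_sessions=2,
        duration_per_trial=2.0,
        shared_drive_correlation=0.9,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return e.generate_cohort(small_config)


@pytest.fixture(scope="session")
def feature_table(small_cohort):
    return e.build_feature_table(small_cohort)


def blend_channel(recordings, target="trapezius", sources=("medial deltoid", "posterior deltoid")):
    """Replace one channel with the exact mean of two others, per recording."""
    out = []
    for rec in recordings:
        channels = dict(rec.channels)
        channels[target] = 0.5 * channels[sources[0]] + 0.5 * channels[sources[1]]
        out.append(dataclasses.replace(rec, channels=channels))
    return out
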