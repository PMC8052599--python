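"""Shared fixtures: small synthetic studies and one cached model fit."""

import numpy as np
import pytest

import mousestress as ms


@pytest.fixture(scope="session")
def small_study():
    """Direct-mode study, 30 subjects x ~12 recordings, true b3 = -0.32."""
    return ms.generate_study(
        ms.StudyParams(seed=101, n_subjects=30, recordings_mean=12, recordings_sd=4)
    )


@pytest.fixture(scope="session")
def small_observations(small_study):
    obs, unmatched_r, unmatched_f = ms.join_observations(
        small_study.reports, small_study.features
    )
    assert not unmatched_r and not unmatched_f
    return obs


@pytest.fixture(scope="session")
def small_fit(small_observations):
    """One cached hierarchical logistic fit shared across summary tests."""
    return ms.fit(
        small_observations,
        ms.ModelSpec(),
        sampler=ms.SamplerConfig(
            seed=7, n_chains=2, n_warmup=400, n_sampling=400, rhat_threshold=1.03
        ),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
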