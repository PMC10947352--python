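import numpy as np
import pytest

import algrowth as ag


@pytest.fixture(scope="session")
def published():
    return {
        "combined": ag.PUBLISHED_COMBINED,
        "EA": ag.PUBLISHED_EA,
        "nonEA": ag.PUBLISHED_NONEA,
    }


@pytest.fixture(scope="session")
def default_corpus():
    """One default-configuration synthetic corpus (28 studies)."""
    return ag.simulate_corpus(ag.SyntheticConfig(seed=20240101))


@pytest.fixture(scope="session")
def default_observations(default_corpus):
    return ag.build_observations(default_corpus)


@pytest.fixture()
def rng():
    return np.random.default_rng(987654321)


def noise_free_observations(params, ages, group="EA", weight=1.0):
    """Exact curve evaluations as equally weighted observations."""
    return [
        ag.WeightedObservation(
            study_id=f"s{i}", group=group, age_mean=float(a),
            al_mean=float(ag.predict_al(params, float(a))),
            se_al=0.05, se_age=0.1, weight=weight)
        for i, a in enumerate(ages)
    ]
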