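import numpy as np
import pytest

from tonecloud import cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Paper-scale cohort with the default (human-ratio) observer."""
    return cohort.simulate_cohort(n_participants=20, n_trials=1000, seed=11)


@pytest.fixture(scope="session")
def strong_cohort():
    """Cohort with a strong implanted 2.2 Hz rhythmic component."""
    sampler = cohort.default_observer_sampler(rhythm_amp=cohort.STRONG_RHYTHM_AMP)
    return cohort.simulate_cohort(n_participants=20, n_trials=1000,
                                  obs_sampler=sampler, seed=21)


@pytest.fixture(scope="session")
def strong_profiles(strong_cohort):
    from tonecloud import revcorr
    rng = np.random.default_rng(77)
    cache = {}
    return [revcorr.perceptual_weights(strong_cohort.participant_trials(p),
                                       n_perm=4000, seed=rng, perm_cache=cache,
                                       participant_id=p)
            for p in range(20)]
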