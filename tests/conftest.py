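import numpy as np
import pytest

from phenorisk.synthetic import (ProfileEmission, ScenarioConfig,
                                 two_profile_scenario)


@pytest.fixture
def tiny_two_profile_config():
    """Small, fast two-profile scenario without a change point."""
    return two_profile_scenario(change_day=None, days=12, rng_seed=11)


@pytest.fixture
def split_config():
    """Two well-separated profiles with a single change at day 60 of 120."""
    return two_profile_scenario(change_day=60, days=120, rng_seed=5)


def make_separated_config(n_profiles=3, days=120, seed=0, sd=0.15, **kwargs):
    """Strongly separated profiles (|dmu| >= 5 sd on every continuous
    dim, binary probs far apart), uniform mixing, no change points."""
    profiles = []
    for k in range(n_profiles):
        lvl = k / max(n_profiles - 1, 1)
        profiles.append(ProfileEmission(
            distance_log_mean=2.0 + 2.0 * k, distance_log_sd=sd,
            home_prob=0.85 - 0.7 * lvl,
            steps_log_mean=3.0 + 2.0 * k, steps_log_sd=sd,
            app_prob=0.15 + 0.7 * lvl))
    uniform = np.full(n_profiles, 1.0 / n_profiles)
    return ScenarioConfig(days_per_patient=days, n_true_profiles=n_profiles,
                          profile_emission_params=profiles,
                          pattern_segments=[(0, uniform)], rng_seed=seed,
                          **kwargs)
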