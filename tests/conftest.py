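import numpy as np
import pytest

from actsense import (
    DEFAULT_TYPE_SET,
    ObservationSet,
    ObserverParams,
    PriorBias,
)
from actsense.simulate import sample_image, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def type_set():
    return DEFAULT_TYPE_SET


@pytest.fixture
def obs_pair():
    """Two observations at the patchy length scale apart, both z=2."""
    D = ObservationSet()
    D.append((0.0, 0.0), 2.0)
    D.append((1.39, 0.0), 2.0)
    return D


@pytest.fixture
def observer_params():
    return ObserverParams(sigma_p=0.5, prior_bias=PriorBias("offset", 0.6), beta=1.5, kappa=0.05)


def random_observations(rng, n, z_scale=1.2, extent=10.0):
    """Random observation set for property tests."""
    D = ObservationSet()
    for _ in range(n):
        D.append(rng.uniform(-extent, extent, 2), rng.normal(0.0, z_scale))
    return D


@pytest.fixture(scope="session")
def random_trials_small():
    """60 balanced random-strategy trials from the default noisy observer."""
    params = ObserverParams(sigma_p=0.5, prior_bias=PriorBias("offset", 0.6), beta=1.5, kappa=0.05)
    return simulate_dataset(60, "random", params, np.random.default_rng(7))


@pytest.fixture(scope="session")
def patchy_image():
    return sample_image("PA", rng=np.random.default_rng(42), seed=42)


# --- shared simulated study data for the acceptance-level analyses -----------

NOISY_OBSERVER = ObserverParams(
    sigma_p=0.5, prior_bias=PriorBias("offset", 0.6), beta=1.5, kappa=0.05
)
IDEAL_SENSOR = ObserverParams(sigma_p=0.17)


@pytest.fixture(scope="session")
def noisy_observer():
    return NOISY_OBSERVER


@pytest.fixture(scope="session")
def paired_strategy_sets():
    """200 paired 25-revealing trials per strategy, on identical images.

    The idealized sensor scores with sigma_p = 0.17, no prior bias, noise-free
    saccades, and observes displayed values; the noisy sensor uses the fitted
    observer model plus measured saccadic variability; heuristics resample the
    noisy sensor's fixation pool.
    """
    from actsense.bas import SaccadeNoiseModel
    from actsense.strategies import build_pool

    n = 200
    rng = np.random.default_rng(1000)
    types = ["PA", "PA", "SH", "SV"] * (n // 4)
    images = [
        sample_image(t, rng=np.random.default_rng(s), seed=int(s))
        for t, s in zip(types, rng.integers(2**31, size=n))
    ]
    sets = {}
    sets["bas"] = simulate_dataset(
        n, "bas", NOISY_OBSERVER, np.random.default_rng(1), counts=(25,),
        noise_model=SaccadeNoiseModel.measured(), images=images,
    )
    sets["ideal_bas"] = simulate_dataset(
        n, "bas", IDEAL_SENSOR, np.random.default_rng(2), counts=(25,),
        observe_displayed=True, images=images,
    )
    sets["random"] = simulate_dataset(
        n, "random", NOISY_OBSERVER, np.random.default_rng(3), counts=(25,), images=images
    )
    pool = build_pool(sets["bas"])
    for i, mode in enumerate(("order", "posterior", "both")):
        sets[f"heuristic:{mode}"] = simulate_dataset(
            n, f"heuristic:{mode}", NOISY_OBSERVER, np.random.default_rng(50 + i),
            counts=(25,), pool=pool, images=images,
        )
    return sets


@pytest.fixture(scope="session")
def bas_trials_per_type():
    """600 noisy-BAS trials (200 per image type, 25 revealings each)."""
    from actsense.bas import SaccadeNoiseModel

    return simulate_dataset(
        600, "bas", NOISY_OBSERVER, np.random.default_rng(77), counts=(25,),
        type_balance="uniform", noise_model=SaccadeNoiseModel.measured(),
    )
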