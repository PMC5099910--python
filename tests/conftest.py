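import numpy as np
import pytest

from thymodyn import default_ground_truth, simulate, simulate_observations
from thymodyn.parameters import ModelSpec, StageParameters
from thymodyn.synthetic import StudyDesign


def make_random_admissible_spec(rng: np.random.Generator) -> ModelSpec:
    """Random parameter set with moderate rates.

    The rate magnitudes keep first-order reference integration (Euler at
    h = 1e-3 day) accurate to well below 1e-3 relative over a 40-day
    horizon, so solver cross-checks measure solver error rather than the
    oracle's own truncation.  The postnatal DP feasibility constraint
    s_N > d_P + s_4 + s_8 is satisfied by construction.
    """

    def stage(postnatal: bool) -> StageParameters:
        d_P, s_4, s_8 = rng.uniform(0.02, 0.08, 3)
        c_range = (0.05, 0.3) if postnatal else (0.5, 2.0)
        return StageParameters(
            b_N=rng.uniform(0.02, 0.1), b_P=rng.uniform(0.02, 0.1),
            b_4=rng.uniform(0.02, 0.1), b_8=rng.uniform(0.02, 0.1),
            c_N=rng.uniform(*c_range), c_P=rng.uniform(*c_range),
            c_48=rng.uniform(*c_range),
            s_N=(d_P + s_4 + s_8) + rng.uniform(0.05, 0.2),
            s_4=s_4, s_8=s_8,
            s_04=rng.uniform(0.02, 0.1), s_08=rng.uniform(0.02, 0.1),
            d_N=rng.uniform(0.02, 0.1), d_P=d_P,
            d_4=rng.uniform(0.02, 0.1), d_8=rng.uniform(0.02, 0.1),
            delta=rng.uniform(0.05, 0.3), tau_N=rng.uniform(0.5, 3.0),
        )

    return ModelSpec(
        prenatal=stage(False), postnatal=stage(True),
        t0=rng.uniform(9.5, 11.0), b0=rng.uniform(1e-3, 1e-2),
        tau_b=rng.uniform(12.0, 16.0),
    )


@pytest.fixture(scope="session")
def ground_truth():
    return default_ground_truth("M1", "V1")


@pytest.fixture(scope="session")
def ground_truth_traj(ground_truth):
    """Full-lifespan trajectory of the pinned M1.V1 ground truth."""
    return simulate(ground_truth)


@pytest.fixture(scope="session")
def noiseless_obs(ground_truth):
    return simulate_observations(ground_truth, StudyDesign(cv=0.0), seed=7)


@pytest.fixture(scope="session")
def noisy_obs(ground_truth):
    return simulate_observations(ground_truth, StudyDesign(cv=0.05), seed=7)
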