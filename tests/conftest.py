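"""Shared fixtures: seeded cohorts and single movies reused across tests."""

import numpy as np
import pytest

from mitoholo import pipeline, simkit

# cohort base seeds, one per condition
WT_SEED, CSA_SEED, FCCP_SEED, KO_SEED = 101, 202, 303, 404
N_WT_MOVIES = 20
N_MOVIES = 10


@pytest.fixture(scope="session")
def wt_cohort():
    """20 wild-type + ferutinin movies, 10 organelles each, default parameters."""
    return pipeline.run_cohort("WT_FERUTININ", N_WT_MOVIES, base_seed=WT_SEED)


@pytest.fixture(scope="session")
def csa_cohort():
    return pipeline.run_cohort("WT_FERUTININ_CSA", N_MOVIES, base_seed=CSA_SEED)


@pytest.fixture(scope="session")
def fccp_cohort():
    return pipeline.run_cohort("FCCP_ONLY", N_MOVIES, base_seed=FCCP_SEED)


@pytest.fixture(scope="session")
def ko_cohort():
    return pipeline.run_cohort("KO_FERUTININ", N_MOVIES, base_seed=KO_SEED)


@pytest.fixture(scope="session")
def wt_movie():
    """One analyzed wild-type movie with its scenario and ground truth."""
    scenario = simkit.make_scenario("WT_FERUTININ", seed=11)
    result, gt = pipeline.simulate_and_analyze(scenario)
    return scenario, result, gt


@pytest.fixture(scope="session")
def noisefree_wt():
    """Noise-free wild-type scenario, rendered stacks and ground truth."""
    scenario = simkit.make_scenario(
        "WT_FERUTININ", seed=13, overrides={"noise.ri_sd": 0.0, "noise.tmrm_sd": 0.0}
    )
    ri, tmrm, gt = simkit.simulate_experiment(scenario)
    return scenario, ri, tmrm, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
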