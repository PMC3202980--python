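import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from arraysense import ArrayParams, ModelConstants
from arraysense.bayes import SamplerSettings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def const() -> ModelConstants:
    return ModelConstants()


@pytest.fixture(scope="session")
def demo_params() -> ArrayParams:
    """A plausible calibrated 4-receptor, 4-ligand array.

    Cross-specific: every receptor binds every ligand with distinct
    affinities; efficacies span near-full agonists to near-antagonists.
    """
    return ArrayParams(
        receptor_ids=["R1", "R2", "R3", "R4"],
        ligand_ids=["L1", "L2", "L3", "L4"],
        dG=[[-8.5, -7.0, -6.0, -5.0],
            [-6.5, -8.0, -5.5, -7.5],
            [-5.0, -6.0, -8.5, -6.5],
            [-7.0, -5.5, -7.0, -8.0]],
        eff=[[0.9, 0.5, 0.3, 0.1],
             [0.2, 0.85, 0.6, 0.4],
             [0.5, 0.15, 0.9, 0.7],
             [0.7, 0.4, 0.2, 0.95]],
        bg=[0.05, 0.05, 0.05, 0.05],
        sigma=[0.02, 0.02, 0.02, 0.02],
    )


@pytest.fixture(scope="session")
def fast_settings() -> SamplerSettings:
    return SamplerSettings(n_live=50, mcmc_steps_per_replacement=15, seed=0)


@pytest.fixture(scope="session")
def mu0_1mM(const) -> float:
    return const.mu_of_concentration(1e-3)
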