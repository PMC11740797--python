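import numpy as np
import pytest

from twinsle import paper_like_config, simulate_cohort
from twinsle.config import SimulationConfig


def scaled_groups(n_pairs: int) -> dict:
    """Group sizes with the study's MZ/DZ mix at a reduced total."""
    base = {"MZ-female": 451, "MZ-male": 222, "DZ-female": 265,
            "DZ-male": 119, "DZ-opposite-sex": 343}
    total = sum(base.values())
    return {g: max(1, round(n * n_pairs / total)) for g, n in base.items()}


@pytest.fixture(scope="session")
def null_cohort():
    """Moderate cohort with baseline variance components and no SLE
    effects (loadings and causal effects all zero)."""
    config = paper_like_config(seed=7).replace(
        n_pairs_by_group=scaled_groups(400),
        gamma=np.zeros(36), w_a=np.zeros(36), w_c=np.zeros(36),
    )
    return simulate_cohort(config)


@pytest.fixture(scope="session")
def paper_cohort():
    """Small cohort under the full study conditions (causal effects plus
    familial confounding)."""
    config = paper_like_config(seed=11).replace(
        n_pairs_by_group=scaled_groups(300)
    )
    return simulate_cohort(config)


@pytest.fixture()
def tiny_config():
    return SimulationConfig(
        n_pairs_by_group={"MZ-female": 4, "DZ-female": 3,
                          "DZ-opposite-sex": 3},
        seed=5,
    )
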