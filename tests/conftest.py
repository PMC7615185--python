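import numpy as np
import pytest

from kcrkit.iontransport import PermeabilitySet, SolutionPair


@pytest.fixture
def physiological_solutions() -> SolutionPair:
    """High extracellular Na+ / high intracellular K+ HEK-style gradients."""
    return SolutionPair(outer={"K": 4.0, "Na": 150.0},
                        inner={"K": 140.0, "Na": 0.0})


@pytest.fixture
def k_selective_perms() -> PermeabilitySet:
    """P_K/P_Na = 25.7, the wild-type-like selectivity."""
    return PermeabilitySet(p_K=1.0, p_Na=1.0 / 25.7, p_Cl=0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230830)
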