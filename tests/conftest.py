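import numpy as np
import pytest

from permeate import (
    BathComposition,
    ConditionSpec,
    GeneratorConfig,
    PermeabilitySet,
)

#: committed once for every seeded test in the suite
SUITE_SEED = 20130405


@pytest.fixture
def bath() -> BathComposition:
    """Standard recording bath: K 5/120, Na 151/14, Cl 143/40 mM, 37 degC."""
    return BathComposition()


@pytest.fixture
def mutant_perms() -> PermeabilitySet:
    return PermeabilitySet(p_k=1.0, p_na=0.13, p_cl=0.6)


@pytest.fixture
def wildtype_perms() -> PermeabilitySet:
    return PermeabilitySet(p_k=1.6, p_na=0.13, p_cl=0.6)


@pytest.fixture
def mutant_spec() -> ConditionSpec:
    return ConditionSpec(genotype="slo3-mutant", state="non-capacitated")


@pytest.fixture
def wildtype_spec() -> ConditionSpec:
    return ConditionSpec(genotype="wild-type", state="non-capacitated")


@pytest.fixture
def noiseless_cfg() -> GeneratorConfig:
    return GeneratorConfig(sigma_mV=0.0, n_replicates=1, dye_sigma_au=0.0, seed=SUITE_SEED)


@pytest.fixture
def default_cfg() -> GeneratorConfig:
    return GeneratorConfig(seed=SUITE_SEED)


def spawn_seeds(n: int, root: int = SUITE_SEED) -> list:
    """Deterministic child seeds below 2**31 for replicate simulations."""
    return [int(s.generate_state(1)[0] % 2**31) for s in np.random.SeedSequence(root).spawn(n)]
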