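import numpy as np
import pytest

from plasmapet import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The study-sized synthetic cohort (58 negative / 60 positive)."""
    return generate_cohort(GeneratorConfig(seed=12345))


@pytest.fixture(scope="session")
def large_cohort():
    """A 10,000-per-group cohort for Monte-Carlo-tight checks."""
    cfg = GeneratorConfig(seed=9).with_sizes(10_000, 10_000)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def huge_cohort():
    """A 100,000-per-group cohort for convergence-to-oracle checks."""
    cfg = GeneratorConfig(seed=9).with_sizes(100_000, 100_000)
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(77)
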