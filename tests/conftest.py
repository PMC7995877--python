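import matplotlib

matplotlib.use("Agg", force=True)

import pytest
from hypothesis import HealthCheck, settings

from mitokit.core import load_genetic_code
from mitokit.fixtures import FixtureParams, generate

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def code5():
    """Invertebrate mitochondrial code (NCBI table 5)."""
    return load_genetic_code(5)


@pytest.fixture(scope="session")
def code1():
    return load_genetic_code(1)


@pytest.fixture(scope="session")
def small_geneset():
    """6 taxa x 4 short genes, strand-labelled, sanity-clean."""
    return generate(
        FixtureParams(
            n_taxa=6,
            genes=[("cox1", 60, "J"), ("cox2", 45, "J"), ("nad1", 50, "N"), ("nad5", 40, "N")],
            seed=11,
        )
    )
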