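import numpy as np
import pytest

from sweepscan.matrix import GenotypeMatrix
from sweepscan.simulate import SimulationConfig, SweepRegionSpec, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_matrix(dosage, populations=None, scaffold="scaf1", spacing=1000):
    """Small GenotypeMatrix from a raw dosage array (rows=samples)."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    samples = [f"s{i:02d}" for i in range(n)]
    population_of = {}
    if populations is not None:
        population_of = dict(zip(samples, populations))
    return GenotypeMatrix.from_arrays(
        samples,
        [scaffold] * m,
        [spacing * (j + 1) for j in range(m)],
        ["A"] * m,
        ["G"] * m,
        dosage,
        population_of,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A modest two-population cohort with one sweep, reused across tests."""
    config = SimulationConfig(
        seed=202,
        scaffolds=[("scaf1", 500_000), ("scaf2", 300_000)],
        populations=[("popA", 20), ("popB", 20)],
        snp_density=1 / 500,
        F_divergence=0.05,
        sweep_regions=[SweepRegionSpec("scaf1", 100_000, 200_000, "all", 0.98)],
        missing_rate=0.03,
        info_fail_fraction=0.05,
    )
    return simulate_cohort(config)
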