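import numpy as np
import pytest

from riskgrader.synthetic import CohortSpec, PlantedGene, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The default 33-sample cohort with 20 planted risk variants (seed 1)."""
    return simulate_cohort(CohortSpec(seed=1))


@pytest.fixture(scope="session")
def planted_ig_cohort():
    """Cohort with one planted important gene per sub-phenotype group."""
    from riskgrader.ig import ALL_GROUPS

    planted = tuple(
        PlantedGene(gene_index=i, subphenotype=sub, side=side)
        for i, (sub, side) in enumerate(ALL_GROUPS)
    )
    return simulate_cohort(
        CohortSpec(seed=11, n_variants=800, planted_ig_genes=planted)
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A quick 12-sample cohort for structural checks."""
    return simulate_cohort(
        CohortSpec(seed=5, n_severe=5, n_mild=7, n_variants=120, n_genes=40,
                   planted_risk_variants=4, risk_delta=0.5)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
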