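import numpy as np
import pandas as pd
import pytest

from sigtool.catalogue import ClassificationSchema, MutationCatalogue
from sigtool.synthetic import (
    SimulationScenario,
    simulate_catalogue,
    simulate_genome_and_vcf,
    synthetic_signatures,
)


@pytest.fixture(scope="session")
def sigs3():
    """Three well-separated (pairwise cosine < 0.5) synthetic SBS96 profiles."""
    return synthetic_signatures("SBS96", 3, seed=1, max_pairwise_cosine=0.5)


@pytest.fixture(scope="session")
def cohort3(sigs3):
    """200-sample Poisson cohort drawn from the three planted signatures."""
    return simulate_catalogue(
        SimulationScenario("c3", sigs3, n_samples=200, seed=7, noise="poisson")
    )


@pytest.fixture(scope="session")
def small_catalogue():
    """Tiny deterministic SBS96 catalogue (3 samples) for fast matrix tests."""
    rng = np.random.default_rng(11)
    schema = ClassificationSchema("SBS96")
    counts = rng.integers(0, 30, size=(96, 3))
    counts[:, 2] += 1  # no all-zero column
    df = pd.DataFrame(counts, index=list(schema.classes), columns=["a", "b", "c"])
    return MutationCatalogue(schema, df)


@pytest.fixture(scope="session")
def toy_genome(tmp_path_factory):
    """Toy genome + VCF + generation-time truth tallies."""
    out = tmp_path_factory.mktemp("toygenome")
    return simulate_genome_and_vcf(
        20_000, n_sbs=60, n_dbs=20, n_indels=40, seed=3, out_dir=str(out)
    )
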