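import numpy as np
import pandas as pd
import pytest

from phenodiv import PhenotypeTable, SimulationConfig, TraitSpec, simulate_phenotypes


@pytest.fixture
def tiny_table() -> PhenotypeTable:
    """Two genotypes x two replicates, one trait; SSg=16, SSe=4 by hand."""
    df = pd.DataFrame({
        "genotype": ["A", "A", "B", "B"],
        "replicate": [1, 2, 1, 2],
        "x": [1.0, 3.0, 5.0, 7.0],
    })
    return PhenotypeTable(data=df, traits=("x",))


@pytest.fixture
def random_table() -> PhenotypeTable:
    """10 genotypes x 4 replicates x 3 traits of seeded noise."""
    rng = np.random.default_rng(42)
    rows = []
    for i in range(10):
        effect = rng.normal(0, [3.0, 1.5, 2.0])
        for j in range(4):
            rows.append({
                "genotype": f"G{i}", "replicate": j + 1,
                "t1": 10 + effect[0] + rng.normal(0, 2),
                "t2": 5 + effect[1] + rng.normal(0, 1),
                "t3": effect[2] + rng.normal(0, 3),
            })
    return PhenotypeTable(data=pd.DataFrame(rows), traits=("t1", "t2", "t3"))


@pytest.fixture(scope="session")
def study_table() -> PhenotypeTable:
    """Full-size synthetic trial: 38 genotypes x 4 replicates x 10 traits."""
    from phenodiv import default_genetic_correlations

    config = SimulationConfig(
        seed=7, genetic_correlations=default_genetic_correlations())
    return simulate_phenotypes(config)


@pytest.fixture
def single_trait_config():
    def make(seed: int, h2: float = 0.9, sigma2_e: float = 1.0,
             g: int = 38, k: int = 4) -> SimulationConfig:
        return SimulationConfig(
            g=g, k=k, seed=seed, populations=(("P", g),),
            traits={"x": TraitSpec(mean=10.0, h2=h2, sigma2_e=sigma2_e)},
        )

    return make
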