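import numpy as np
import pytest

from panoric import (
    OrthologFamily,
    PanGenome,
    SimulationConfig,
    simulate_cohort,
    simulate_pangenome,
)


@pytest.fixture(scope="session")
def toy_pan() -> PanGenome:
    """Hand-built 4-strain pan-genome for enumerable expectations.

    fam0 spans all strains; fam1 = focal A + 2 others; fam2 is A-specific;
    fam3 has a paralog pair in B; fam4 is low-connectivity core.
    """
    return PanGenome(
        strains=["A", "B", "C", "D"],
        families=[
            OrthologFamily("fam0", {"A": ["a0"], "B": ["b0"], "C": ["c0"], "D": ["d0"]}, 0.95),
            OrthologFamily("fam1", {"A": ["a1"], "B": ["b1"], "C": ["c1"]}, 1.0),
            OrthologFamily("fam2", {"A": ["a2"]}, 1.0),
            OrthologFamily("fam3", {"B": ["b3", "b3x"], "C": ["c3"]}, 0.5),
            OrthologFamily("fam4", {"A": ["a4"], "B": ["b4"], "C": ["c4"], "D": ["d4"]}, 0.6),
        ],
    )


SMALL_COHORT = SimulationConfig(
    n_strains=6,
    n_families=500,
    genes_per_strain=250,
    genome_length=500_000,
    positional_bias_beta=-5.0,
    seed=42,
)


@pytest.fixture(scope="session")
def small_cohort():
    """One simulated cohort (with sequences) reused across read-only tests."""
    return simulate_cohort(SMALL_COHORT)


@pytest.fixture(scope="session")
def small_pangenome():
    cfg = SimulationConfig(
        n_strains=8, n_families=400, genes_per_strain=200, genome_length=400_000, seed=7
    )
    return cfg, *simulate_pangenome(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
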