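import numpy as np
import pandas as pd
import pytest

from indelenrich.simulate import (
    SimulationConfig,
    simulate_trait_associations,
    simulate_variant_genome,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_dataset():
    """A compact synthetic cohort with a planted enrichment (lambda = 1)."""
    cfg = SimulationConfig(
        n_loci=30, variants_per_locus=40, background_variants=800,
        lambda_true=1.0, seed=11,
    )
    genome, coding, lowc = simulate_variant_genome(cfg)
    sumstats, truth = simulate_trait_associations(genome, cfg, coding)
    return {"config": cfg, "genome": genome, "coding": coding,
            "lowc": lowc, "sumstats": sumstats, "truth": truth}


@pytest.fixture
def variant_table():
    return pd.DataFrame(
        {
            "CHROM": ["1", "1", "2", "2", "3"],
            "POS": [100, 200, 150, 300, 50],
            "REF": ["A", "TGCTG", "T", "G", "C"],
            "ALT": ["T", "T", "TAC", "A", "G"],
            "MAF": [0.05, 0.005, 0.005, 0.3, 0.02],
            "RSQR": [0.40, 0.50, 0.70, 0.95, 0.25],
        }
    )
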