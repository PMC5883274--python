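import numpy as np
import pandas as pd
import pytest

from songmark import ArtifactRates, SimulationConfig, generate_probe_library


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        seed=1,
        n_genes=100,
        probes_per_gene=2,
        artifact_rates=ArtifactRates(
            polyT=0.1, multilocus=0.05, unaligned=0.05, chrun_secondary=0.05
        ),
    )


@pytest.fixture(scope="session")
def small_library(small_config):
    return generate_probe_library(small_config)


@pytest.fixture()
def toy_models():
    """Five gene models on one chromosome, both strands, for annotation
    boundary checks."""
    return pd.DataFrame(
        {
            "gene_id": ["gA", "gB", "gC", "gD", "gE"],
            "symbol": ["A", "B", "C", "D", "E"],
            "chrom": ["chr1"] * 5,
            "strand": ["+", "+", "-", "+", "-"],
            "start": [1000, 20000, 40000, 60000, 80000],
            "end": [5000, 25000, 45000, 65000, 85000],
        }
    )
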