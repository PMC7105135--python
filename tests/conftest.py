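"""Shared fixtures: small synthetic datasets generated at test time."""

import warnings

import pytest

from wolbmeth.config import SimConfig
from wolbmeth import simulate

# the conversion-efficiency warning fires routinely at the 99.8% boundary
warnings.filterwarnings("ignore", message="bisulfite conversion efficiency")


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(seed=11, n_cpgs=1_500, n_genes=100, n_parental_snps=600,
                     n_lambda_sites=500)


@pytest.fixture(scope="session")
def small_truth(small_config):
    genes, exons, panel, genotypes, truth = simulate.simulate_genome_and_annotation(small_config)
    return {"genes": genes, "exons": exons, "panel": panel,
            "genotypes": genotypes, "truth": truth}


@pytest.fixture(scope="session")
def small_input_dir(tmp_path_factory, small_config):
    from wolbmeth.pipeline import simulate_to_dir

    d = tmp_path_factory.mktemp("inputs")
    simulate_to_dir(small_config, d)
    return d
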