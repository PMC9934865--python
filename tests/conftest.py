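import numpy as np
import pytest

from perduraflow import AnalysisConfig, run_pipeline
from perduraflow.synthetic import default_gene_params, simulate_paired_datasets

# QC threshold scaled to the simulator's 300-gene universe (the genome-scale
# default of 200 assumes ~15k genes)
SIM_QC_MIN_GENES = 30


@pytest.fixture(scope="session")
def small_sim():
    """120-gene, 600-cell paired simulation: fast input for unit tests."""
    params = default_gene_params(n_genes=120, seed=1)
    datasets, truth = simulate_paired_datasets(params, n_cells_per_modality=600, seed=1)
    return params, datasets, truth


@pytest.fixture(scope="session")
def small_run(small_sim):
    """Full pipeline on the small simulation."""
    _, datasets, truth = small_sim
    config = AnalysisConfig(seed=1, min_genes_per_cell=SIM_QC_MIN_GENES)
    # re-simulate inside run_pipeline for isolation from fixture mutation
    return run_pipeline(config, simulate=True, n_genes=120, n_cells_per_modality=600)


@pytest.fixture(scope="session")
def full_run():
    """The reference-scale study: 300 genes, 3,000 cells per modality, seed 1."""
    config = AnalysisConfig(seed=1, min_genes_per_cell=SIM_QC_MIN_GENES)
    return run_pipeline(config, simulate=True, n_genes=300, n_cells_per_modality=3000)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
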