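import numpy as np
import pytest

from dgecompare.containers import CountMatrix, CountUnit, Method, SampleMeta
from dgecompare.simulate import SimulationConfig, generate_gene_table, simulate_paired_experiment


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Small paired experiment: quick to simulate, big enough for statistics."""
    return SimulationConfig(
        n_genes=3000,
        n_control=4,
        n_treated=3,
        library_size_mean=3e5,
        dispersion=0.1,
        n_de_genes=300,
        de_log2fc_mean=1.5,
        de_log2fc_sd=0.3,
        detection_dropout=0.2,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_experiment(small_config):
    return simulate_paired_experiment(small_config)


def make_matrix(counts, unit=CountUnit.READ, method=Method.CONVENTIONAL, treatments=None):
    counts = np.asarray(counts)
    n_genes, n_samples = counts.shape
    if treatments is None:
        treatments = ["CTRL"] * n_samples
    reps: dict = {}
    samples = []
    for j, t in enumerate(treatments):
        reps[t] = reps.get(t, 0) + 1
        samples.append(SampleMeta(f"S{j}", method, t, reps[t]))
    genes = [f"G{i:03d}" for i in range(n_genes)]
    return CountMatrix(genes, samples, counts, unit)
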