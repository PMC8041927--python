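import numpy as np
import pytest

from m6acall import GeneModel, SimulationConfig, simulate_fragments, simulate_gene_models


def random_gene_model(rng, max_exons=10, max_len=2000, gene_id="g", tx_id="t"):
    """A random valid multi-exon GeneModel for property tests."""
    n_exons = int(rng.integers(1, max_exons + 1))
    length = int(rng.integers(n_exons, max_len + 1))
    if n_exons > 1:
        cuts = np.sort(rng.choice(np.arange(1, length), size=n_exons - 1, replace=False))
        sizes = np.diff(np.concatenate(([0], cuts, [length])))
    else:
        sizes = np.array([length])
    introns = rng.integers(1, 300, size=max(n_exons - 1, 0))
    starts = np.empty(n_exons, dtype=np.int64)
    ends = np.empty(n_exons, dtype=np.int64)
    pos = int(rng.integers(0, 1000))
    for j, size in enumerate(sizes):
        starts[j] = pos
        ends[j] = pos + int(size)
        pos = int(ends[j]) + (int(introns[j]) if j < n_exons - 1 else 0)
    strand = "+" if rng.random() < 0.5 else "-"
    return GeneModel(gene_id, tx_id, "chrT", strand, starts, ends)


@pytest.fixture
def two_exon_plus():
    return GeneModel("g1", "t1", "chr1", "+",
                     np.array([0, 200]), np.array([100, 300]))


@pytest.fixture
def two_exon_minus():
    return GeneModel("g2", "t2", "chr1", "-",
                     np.array([0, 200]), np.array([100, 300]))


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated dataset shared across tests (seed-fixed)."""
    config = SimulationConfig(seed=11, n_genes=12, shared_down=3, shared_up=2)
    models, truth = simulate_gene_models(config)
    ip_df, input_df = simulate_fragments(models, truth, config)
    return config, models, truth, ip_df, input_df
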