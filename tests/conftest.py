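import numpy as np
import pytest

from crmnet.synthetic import TruthConfig, generate_truth, simulate_replicates


@pytest.fixture(scope="session")
def small_truth():
    """Tiny instance: genome small enough that chance motif hits are
    vanishingly unlikely, so sequence-level recovery is exact."""
    cfg = TruthConfig(
        n_chroms=2, chrom_length=5000, n_tfs=3, n_tgs=6, n_res=12,
        re_width=200, motif_width=10, edge_density=0.4, window=2000,
        n_panel=60, sigma_e=0.0, seed=3,
    )
    return generate_truth(cfg)


@pytest.fixture(scope="session")
def medium_truth():
    """Mid-size instance for consensus and annotation behavior."""
    cfg = TruthConfig(
        n_chroms=2, chrom_length=50_000, n_tfs=10, n_tgs=50, n_res=150,
        re_width=200, motif_width=10, edge_density=0.1, window=10_000,
        n_panel=80, seed=11,
    )
    return generate_truth(cfg)


@pytest.fixture(scope="session")
def medium_replicates(medium_truth):
    networks, samples = simulate_replicates(medium_truth, seed=12)
    return networks


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
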