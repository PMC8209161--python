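import numpy as np
import pytest

from ctmeth.simulator import SimConfig, simulate_genome_and_panel


@pytest.fixture(scope="session")
def small_panel():
    """Ten-probe synthetic panel shared by read-level tests.

    Products are kept above 100 bp: simulated reads are bare amplicons
    (no sequencing adapters), so shorter products would lose every read to
    the strict >100 bp length filter.
    """
    cfg = SimConfig(seed=42, n_probes=10, cpgs_per_probe=(3, 10),
                    amplicon_len=(105, 150))
    _, panel = simulate_genome_and_panel(cfg)
    return panel


@pytest.fixture(scope="session")
def brca1_panel():
    """Panel whose last probe is a BRCA1 probe (MI-exempt)."""
    cfg = SimConfig(seed=7, n_probes=6, cpgs_per_probe=(3, 8),
                    amplicon_len=(105, 150), include_brca1=True)
    _, panel = simulate_genome_and_panel(cfg)
    return panel


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
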