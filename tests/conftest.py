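import numpy as np
import pytest

from hicforge.digest import build_fend_table
from hicforge.enzymes import BUILTIN_ENZYMES
from hicforge.simulate import SimConfig, simulate_genome


@pytest.fixture(scope="session")
def hindiii():
    return BUILTIN_ENZYMES["HindIII"]


@pytest.fixture(scope="session")
def small_dataset():
    """Two-chromosome synthetic genome with its FEND table (desk scale)."""
    cfg = SimConfig(seed=11, n_chroms=2, chrom_length=100_000,
                    sites_per_chrom=40, n_pairs=5_000, bin_size=5_000)
    genome, truth = simulate_genome(cfg)
    fends = build_fend_table(genome, cfg.get_enzyme(), map_k=20, map_window=100)
    return cfg, genome, truth, fends


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
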