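import numpy as np
import pytest

from ndrchip.io import GenomeLayout, SampleMeta, make_fragment_set
from ndrchip.pipeline import simulate_and_run
from ndrchip.simulate import ScenarioConfig, build_scenario


@pytest.fixture
def layout():
    return GenomeLayout(("chrI", "chrII"), (1000, 2000))


@pytest.fixture
def rng():
    return np.random.default_rng(20240117)


def random_fragments(layout, rng, n=200, min_len=20, max_len=300, meta=None):
    """Uniform random fragments valid against a layout (shared test helper)."""
    idx = rng.integers(0, len(layout.names), size=n)
    chrom = np.array(layout.names, dtype="U32")[idx]
    chrom_len = np.array(layout.lengths)[idx]
    lengths = rng.integers(min_len, max_len + 1, size=n)
    lengths = np.minimum(lengths, chrom_len)
    start = (rng.random(n) * (chrom_len - lengths)).astype(np.int64)
    return make_fragment_set(layout, chrom, start, start + lengths,
                             meta or SampleMeta())


@pytest.fixture
def small_truth():
    """A fast, 12-gene scenario for unit-level simulation tests."""
    cfg = ScenarioConfig(chromosome_length=30_000, n_5prime_sites=12,
                         n_orf_sites=2, n_rpg=2, n_fragments=20_000,
                         tdna_per_chromosome=1)
    return build_scenario(cfg, seed=7)


@pytest.fixture(scope="session")
def demo():
    """One full-scale demo run (the study conditions) shared across tests."""
    return simulate_and_run(seed=11)
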