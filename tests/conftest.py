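import numpy as np
import pytest

from polyterm.model import ConditionParams
from polyterm.simulate import GenomeConfig, build_toy_genome


@pytest.fixture(scope="session")
def bundle():
    """Default toy genome shared across tests."""
    return build_toy_genome(GenomeConfig(seed=1))


@pytest.fixture(scope="session")
def small_bundle():
    """A compact genome small enough for the brute-force toy aligner."""
    cfg = GenomeConfig(
        chrom_length=120_000, seed=2,
        n_multi_exon_genes=1, n_single_exon_genes=1, n_non_apa_genes=1,
        n_line1_full=1, n_line1_frag=1, n_sine=1, n_ltr=1,
        n_duplicated_segments=1, gene_gap=6000,
    )
    return build_toy_genome(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def clean_params(n_reads, seed, **kwargs):
    """Condition parameters with all background sources switched off."""
    defaults = dict(
        readthrough_prob=0.0, line1_rate=0.0, sine_rate=0.0, ltr_rate=0.0,
        intergenic_rate=0.0, junk_rate=0.0, unspliced_frac=0.0,
    )
    defaults.update(kwargs)
    return ConditionParams(n_reads=n_reads, seed=seed, **defaults)
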