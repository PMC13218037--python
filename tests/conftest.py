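import numpy as np
import pytest

from duochrome.io import ReferenceGenome, VariantCall
from duochrome.synthetic_data import CONTIG, ExperimentConfig, simulate_reference


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_genome():
    """Hand-written two-contig reference for exact-context assertions."""
    return ReferenceGenome(
        {
            "c1": "AACCTGGTTACGTACGTACG",
            "c2": "TTGGAACCATTTTGGGCCCA",
        }
    )


@pytest.fixture
def sim_genome():
    """20 kb seeded i.i.d. reference (single contig named sim1)."""
    return simulate_reference(20_000, gc_fraction=0.41, seed=11)


@pytest.fixture
def fast_config():
    """Reduced-size experiment config for smoke/CLI tests."""
    return ExperimentConfig(genome_length=30_000, n_true_mutations=120, seed=3)


def make_call(genome, contig, pos0, alt, ad=5, dp=30, platform=""):
    ref = genome.contigs[contig][pos0]
    return VariantCall(contig, pos0 + 1, ref, alt, ad=ad, dp=dp, platform=platform)
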