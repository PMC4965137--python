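import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from zeitshift.fragnorm import FragmentSet
from zeitshift.synthgen import SimDesign, generate_chip_fragments, generate_genome


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_design():
    return SimDesign(n_genes=20, depth_per_sample=20_000, seed=7)


@pytest.fixture(scope="session")
def small_study(small_design):
    """Genome, gene models and truth for a 20-gene study."""
    return generate_genome(small_design)


@pytest.fixture(scope="session")
def small_samples(small_design, small_study):
    genome, genes, truth = small_study
    return generate_chip_fragments(genes, truth, small_design)


def make_fragments(rows):
    """FragmentSet from (chrom, start, end, strand) tuples."""
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])
    return FragmentSet(sample_id="test", genotype="P1", zt="ZT3",
                       replicate=1, treatment="ChIP", fragments=df)


@pytest.fixture
def fragment_factory():
    return make_fragments
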