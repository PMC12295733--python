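import numpy as np
import pytest

from ecckit.annotation import build_catalog
from ecckit.io_formats import GenomeLayout
from ecckit.simulate import (
    SimulationConfig,
    simulate_cohort,
    simulate_genome_and_tracks,
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(seed=3, n_chroms=2, chrom_length_bp=300_000,
                            n_tumor=6, n_normal=4, ecc_per_sample=120.0)


@pytest.fixture(scope="session")
def small_genome(small_config):
    layout, tracks = simulate_genome_and_tracks(small_config)
    return layout, tracks


@pytest.fixture(scope="session")
def small_catalog(small_genome):
    layout, tracks = small_genome
    return build_catalog(
        tracks["gene_model"], tracks["enhancer"], tracks["dhs"],
        tracks["cpg_island"], tracks["repeats"], layout,
    )


@pytest.fixture(scope="session")
def default_cohort():
    """The study-scale synthetic cohort (81 tumor / 33 normal, seed 7)."""
    return simulate_cohort(SimulationConfig(seed=7))


@pytest.fixture
def toy_layout():
    return GenomeLayout(("chrA", "chrB"), {"chrA": 1_000_000, "chrB": 500_000})


def random_ecc_frame(layout, n, rng, min_len=80, max_len=2000):
    """Uniformly placed random eccDNA intervals for engine tests."""
    import pandas as pd

    chroms = rng.choice(list(layout.names), size=n)
    lengths = rng.integers(min_len, max_len, size=n)
    lens = np.asarray([layout.length(c) for c in chroms])
    starts = (rng.random(n) * np.maximum(1, lens - lengths)).astype(np.int64)
    return pd.DataFrame(
        {"chrom": chroms, "start": starts, "end": starts + lengths}
    )
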