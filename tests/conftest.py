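import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")

from chromdyn import (
    BinarizedTracks,
    ChromatinStateModel,
    GenomeBins,
    StateSegmentation,
    SyntheticConfig,
    load_archetypes,
    simulate,
)


@pytest.fixture
def small_bins() -> GenomeBins:
    return GenomeBins(("chr1", "chr2"), (10_000, 6_000), bin_width=200)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def two_state_model() -> ChromatinStateModel:
    """Well-separated 2-state, 3-mark model used across HMM tests."""
    return ChromatinStateModel(
        emission=np.array([[0.9, 0.9, 0.1], [0.1, 0.1, 0.9]]),
        transition=np.array([[0.95, 0.05], [0.05, 0.95]]),
        initial=np.array([0.5, 0.5]),
        mark_names=("m1", "m2", "m3"),
    )


def random_segmentation(bins: GenomeBins, n_states: int, time_points, seed: int) -> StateSegmentation:
    rng = np.random.default_rng(seed)
    labels = {
        tp: rng.integers(1, n_states + 1, size=bins.total_bins) for tp in time_points
    }
    return StateSegmentation(bins, tuple(time_points), labels, n_states)


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete synthetic dataset shared by read-only tests."""
    cfg = SyntheticConfig(
        n_chromosomes=2,
        chromosome_length=400_000,
        n_states=4,
        n_marks=4,
        mark_names=("H3K27me3", "H3K4me3", "H3K36me3", "CTCF"),
        n_genes=95,
        module_spec=[(a, 5, 1.0) for a in sorted(load_archetypes())],
        dynamics_coupling={1: 0.4, 2: 0.01},
        gene_length_log_mean=float(np.log(1500.0)),
        gene_length_log_sd=0.5,
        seed=77,
    )
    return simulate(cfg)
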