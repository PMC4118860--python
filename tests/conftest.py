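import numpy as np
import pytest

from pairedcna import (
    CNProfile,
    ProbeGrid,
    SampleMeta,
    SimParams,
    make_toy_genome,
)


@pytest.fixture
def small_params() -> SimParams:
    """Small genome for fast unit tests: 2 chromosomes x 10 Mb, 50 kb spacing."""
    return SimParams(
        n_chrom=2,
        chrom_length_bp=10_000_000,
        probe_spacing_bp=50_000,
        cna_length_log_mean=14.0,  # ~1.2 Mb median events fit a 10 Mb chromosome
        cna_length_log_sd=0.5,
        seed=0,
    )


@pytest.fixture
def small_grid(small_params) -> ProbeGrid:
    return make_toy_genome(small_params)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def profile_from(grid: ProbeGrid, values, sample_id="S1", patient="P1",
                 tissue="tumour", subtype="TNBC") -> CNProfile:
    return CNProfile(grid, np.asarray(values, float),
                     SampleMeta(sample_id, patient, tissue, subtype))


@pytest.fixture
def make_profile():
    return profile_from
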