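import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from chromcompare.signal import build_coverage, normalize_track
from chromcompare.synthetic import SimConfig, generate_fixture

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def truth():
    """Default-scale synthetic study; shared across tests (generation ~5 s)."""
    return generate_fixture(seed=11)


@pytest.fixture(scope="session")
def h3_track(truth):
    track = build_coverage(
        truth.h3_reads,
        truth.config.fragment_length,
        truth.chrom_sizes,
        name="h3",
    )
    return normalize_track(track)


@pytest.fixture(scope="session")
def competition_truth():
    """Fixture with 100 planted 2-fold-down and 400 unchanged shared sites."""
    cfg = SimConfig(
        n_chroms=2,
        chrom_length=2_000_000,
        n_genes=120,
        n_a_sites=500,
        n_b_sites=600,
        n_shared=500,
        n_down_shared=100,
        n_up_shared=0,
        h3_background_reads=20_000,
        chip_background_reads=5_000,
    )
    return generate_fixture(cfg, seed=23)


@pytest.fixture(scope="session")
def small_config():
    """Cheap configuration for end-to-end pipeline tests."""
    return SimConfig(
        n_chroms=2,
        chrom_length=400_000,
        n_genes=60,
        n_a_sites=60,
        n_b_sites=150,
        n_shared=40,
        min_site_spacing=2_000,
        n_down_shared=10,
        n_up_shared=5,
        h3_reads_per_site=120.0,
        h3_background_reads=5_000,
        chip_background_reads=2_000,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
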