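import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

from bsamap import SimConfig, simulate_dataset  # noqa: E402


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def small_config():
    """A desk-scale cross: 3 scaffolds, one above the window cutoff."""
    return SimConfig(
        scaffolds={"sA": 1_200_000, "sB": 400_000, "sC": 700_000},
        snp_spacing_bp=8_000,
        causal=("sA", 600_000),
        n_mut_embryos=30,
        n_wt_embryos=30,
        depth_mean=30.0,
        error_rate=0.002,
        cm_per_mb=1.2,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


def random_pooled_sites(rng, n, depth_low=0, depth_high=40):
    """Randomized PooledSites spanning the caller's decision boundaries."""
    from bsamap import PooledSite
    from bsamap.pileup_io import BASES

    sites = []
    for i in range(n):
        wt = {b: int(c) for b, c in zip(BASES, rng.integers(0, depth_high // 2, 4))}
        mut = {b: int(c) for b, c in zip(BASES, rng.integers(0, depth_high // 2, 4))}
        if rng.random() < 0.3:  # sharpen: near-monomorphic mutant pool
            base = BASES[rng.integers(0, 4)]
            mut = {b: 0 for b in BASES}
            mut[base] = int(rng.integers(depth_low, depth_high))
            other = BASES[rng.integers(0, 4)]
            mut[other] += int(rng.integers(0, 4))
        sites.append(
            PooledSite(
                chrom="s1",
                pos=i + 1,
                ref_base=BASES[rng.integers(0, 4)],
                wt=wt,
                mut=mut,
            )
        )
    return sites
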