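import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lrmeta import (
    CommunityProfile,
    GenomeEntry,
    SimulationConfig,
)
from lrmeta.simulate import simulate_community

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return (
        rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length)
        .tobytes()
        .decode("ascii")
    )


def make_community(seed: int, sizes, molarities=None) -> CommunityProfile:
    rng = np.random.default_rng(seed)
    genomes = [
        GenomeEntry(id=f"g{i}", length_bp=n, sequence=random_sequence(rng, n))
        for i, n in enumerate(sizes)
    ]
    if molarities is None:
        molarities = [1.0] * len(sizes)
    return CommunityProfile.from_molarities(genomes, molarities)


@pytest.fixture(scope="session")
def toy_community() -> CommunityProfile:
    """Two equal-abundance 100 kb genomes."""
    return make_community(101, [100_000, 100_000])


@pytest.fixture(scope="session")
def toy_sim(toy_community):
    """Simulated toy library: C_F=30, C_R=0.3 (C=9X per genome), seed 1."""
    cfg = SimulationConfig(c_f=30.0, c_r=0.3, seed=1)
    fragments, partitions, pairs = simulate_community(toy_community, cfg)
    return {
        "community": toy_community,
        "cfg": cfg,
        "fragments": fragments,
        "partitions": partitions,
        "pairs": pairs,
    }


@pytest.fixture(scope="session")
def titration_sim():
    """Scaled-down titration library: three 200 kb genomes at equal
    abundance, C_F=30, C_R=0.3, mu_FL=10 kb, N_F/P=10, seed 1."""
    community = make_community(202, [200_000] * 3)
    cfg = SimulationConfig(
        c_f=30.0, c_r=0.3, mu_fl=10_000.0, n_fp=10.0, seed=1
    )
    fragments, partitions, pairs = simulate_community(community, cfg)
    return {
        "community": community,
        "cfg": cfg,
        "fragments": fragments,
        "partitions": partitions,
        "pairs": pairs,
    }


@pytest.fixture(scope="session")
def demo_report(tmp_path_factory):
    from lrmeta.demo import run_demo

    out = tmp_path_factory.mktemp("demo")
    return run_demo(out, seed=0), out
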