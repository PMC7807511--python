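"""Shared fixtures: synthetic benchmarks reused across test modules."""

import numpy as np
import pytest

from phagehost import HostCatalog, SyntheticConfig, generate_benchmark


@pytest.fixture(scope="session")
def benchmark():
    """Reference benchmark: 20 genera x 2 hosts x 2 viruses, 50 kb hosts,
    10 kb viruses, divergence 0.5, virus noise 0.05, seed 0."""
    return generate_benchmark(SyntheticConfig())


@pytest.fixture(scope="session")
def bench_stores(benchmark):
    """(virus ProfileStore, host ProfileStore, HostCatalog) at k=4."""
    virus = benchmark.virus_profiles(4)
    host = benchmark.host_profiles(4)
    return virus, host, HostCatalog(host, benchmark.host_lineages)


@pytest.fixture(scope="session")
def small_benchmark():
    """Cheap benchmark for protocol and CLI tests: 8 genera x 2 hosts x 1 virus."""
    return generate_benchmark(
        SyntheticConfig(
            n_genera=8,
            hosts_per_genus=2,
            viruses_per_host=1,
            host_length=20_000,
            virus_length=5_000,
            seed=1,
        )
    )


@pytest.fixture(scope="session")
def small_stores(small_benchmark):
    virus = small_benchmark.virus_profiles(4)
    host = small_benchmark.host_profiles(4)
    return virus, host, HostCatalog(host, small_benchmark.host_lineages)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
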