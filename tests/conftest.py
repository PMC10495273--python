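"""Shared fixtures: synthetic benchmarks built once per session."""

import pytest

import demetax as dx

BENCH_SEED = 1  # fixed benchmark seed used throughout the suite


@pytest.fixture(scope="session")
def capsicum_bench():
    return dx.make_benchmark("capsicum_like", BENCH_SEED)


@pytest.fixture(scope="session")
def capsicum_curated(capsicum_bench):
    """The flagship benchmark after NA trimming and duplicate collapsing."""
    b = capsicum_bench
    m, a = dx.trim_invalid(b.matrix, b.labels)
    m, a, mapping = dx.collapse_duplicates(m, a, b.duplicates, BENCH_SEED)
    return m, a, mapping, b


@pytest.fixture(scope="session")
def toy_bench():
    return dx.make_benchmark("two_deme_toy", BENCH_SEED)


@pytest.fixture(scope="session")
def tiny_bench():
    return dx.make_benchmark("tiny_worked", BENCH_SEED)
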