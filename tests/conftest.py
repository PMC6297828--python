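"""Shared fixtures: session-scoped synthetic benchmarks.

The default benchmark (5 control + 10 transgenic mice, 8 time points,
power-law attractor sizes with exponent 3) is generated and clustered once
per session; tests that only need activity labels use the ground-truth
clustering to avoid re-running the greedy pass.
"""

import numpy as np
import pytest

from tcranet.clustering import attractor_activity, cluster_repertoire
from tcranet.simulate import SimConfig, generate


@pytest.fixture(scope="session")
def benchmark():
    """Default synthetic benchmark experiment (seed 0)."""
    return generate(SimConfig(seed=0))


@pytest.fixture(scope="session")
def benchmark_clustered(benchmark):
    """(AttractorSet, ActivityMatrix) from actually clustering the benchmark."""
    records = benchmark.clone_records()
    totals = {}
    for r in records:
        totals[r.junction_aa] = totals.get(r.junction_aa, 0) + r.count
    aset = cluster_repertoire(totals)
    return aset, attractor_activity(aset, records)


@pytest.fixture(scope="session")
def benchmark_truth_activity(benchmark):
    """(AttractorSet, ActivityMatrix) from the generator's ground truth."""
    return benchmark.truth_activity()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
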