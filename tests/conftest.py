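import numpy as np
import pytest

from mirkinet import synthetic_data as sd
from mirkinet.inference import InferenceConfig


@pytest.fixture(scope="session")
def four_targets():
    return sd.example_four_target_params()


@pytest.fixture(scope="session")
def small_spec():
    """A reduced benchmark: 40 targets, 800 cells, default noise."""
    return sd.BenchmarkSpec(n_targets=40, n_cells=800, seed=11)


@pytest.fixture(scope="session")
def small_bench(small_spec):
    return sd.generate_benchmark(small_spec)


@pytest.fixture(scope="session")
def small_config():
    """Inference thresholds with reference pools scaled to 800 cells."""
    return InferenceConfig(n_low=320, n_high=40)


@pytest.fixture(scope="session")
def match_truth():
    """Align a benchmark's true parameters with an inference result."""

    def _match(bench, result):
        idx = {p.id: i for i, p in enumerate(bench.params)}
        sel = np.array([idx[g] for g in result.gene_ids])
        return bench.true_afc[sel], bench.true_km[sel]

    return _match
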