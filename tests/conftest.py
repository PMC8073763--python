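import numpy as np
import pytest
from hypothesis import settings

from envsync.pipeline import PipelineConfig, process_record
from envsync.synth import benchmark_configs, generate_record

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


def dft_hilbert_imag(x: np.ndarray) -> np.ndarray:
    """Independent O(n^2) direct-DFT Hilbert oracle (even n)."""
    n = len(x)
    k = np.arange(n)
    W = np.exp(-2j * np.pi * np.outer(k, k) / n)
    F = W @ x
    h = np.zeros(n)
    h[0] = h[n // 2] = 1.0
    h[1 : n // 2] = 2.0
    analytic = (np.conj(W) @ (h * F)) / n
    return analytic.imag


def brute_force_extrema(x: np.ndarray, min_separation: int, positive: bool = True) -> list[int]:
    """Oracle: scan strict interior local extrema of the right sign, then
    greedily enforce the separation left to right."""
    y = x if positive else -x
    cand = [
        i for i in range(1, len(y) - 1)
        if y[i - 1] < y[i] > y[i + 1] and y[i] > 0
    ]
    keep, last = [], -np.inf
    for i in cand:
        if i - last >= min_separation:
            keep.append(i)
            last = i
    return keep


@pytest.fixture(scope="session")
def benchmark_plv():
    """PLV series + annotations for the default 10-record labeled benchmark
    (seed 1, hour-long, 23 channels, 6 records with one seizure each).

    Records are generated and reduced one at a time to bound memory; the
    expensive part is shared by every test that needs the benchmark.
    """
    cfg = PipelineConfig()
    prepared = []
    for sc in benchmark_configs(seed=1):
        record, anns = generate_record(sc)
        prepared.append((record.record_id, process_record(record, cfg), anns))
        del record
    return prepared
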