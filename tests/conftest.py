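import numpy as np
import pytest


@pytest.fixture(autouse=True)
def _single_threaded_blas(monkeypatch):
    # keep timings and results stable on shared machines
    monkeypatch.setenv("OMP_NUM_THREADS", "1")


@pytest.fixture
def rng():
    return np.random.default_rng(0)
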