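import numpy as np
import pytest

from hdcfusion import DatasetLayout, ModalityConfig, make_layout


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def amigos_layout():
    return make_layout("amigos_like")


@pytest.fixture
def deap_layout():
    return make_layout("deap_like")


@pytest.fixture
def tiny_layout():
    """Three small modalities; odd channel counts avoid bundling ties."""
    return DatasetLayout(
        [ModalityConfig("a", 3), ModalityConfig("b", 5), ModalityConfig("c", 7)]
    )


def bits(s: str) -> np.ndarray:
    """'10110100' -> uint8 array, index 0 first."""
    return np.array([int(c) for c in s], dtype=np.uint8)
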