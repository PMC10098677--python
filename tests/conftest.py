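import logging

import numpy as np
import pytest

from pcamiss import ObservedData, Subspace


@pytest.fixture(autouse=True)
def _quiet_warnings():
    """Generator/estimator warnings are expected in sparse tests; keep logs clean."""
    logging.disable(logging.WARNING)
    yield
    logging.disable(logging.NOTSET)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def random_subspace(d: int, K: int, rng) -> Subspace:
    q, r = np.linalg.qr(rng.standard_normal((d, K)))
    return Subspace(q * np.sign(np.diag(r)))


def random_rotation(K: int, rng) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((K, K)))
    return q * np.sign(np.diag(r))


def mcar_data(y: np.ndarray, p: float, rng) -> ObservedData:
    mask = (rng.random(y.shape) < p).astype(np.int8)
    return ObservedData.from_full(y, mask)
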