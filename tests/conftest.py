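import numpy as np
import pytest

import segpipe as sp
from segpipe import data_io, metrics, model


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(autouse=True)
def _clean_registries():
    """Keep the global metric/interface/architecture registries pristine."""
    yield
    metrics.reset_metrics()
    model.reset_architectures()
    data_io.clear_data_interfaces()


@pytest.fixture
def phantom3():
    """One deterministic three-class 32^3 phantom."""
    return sp.generate_phantom(sp.PhantomConfig(seed=7), sample_id="fix")


@pytest.fixture
def phantom_dataset(tmp_path):
    """Three phantoms written in the on-disk NIfTI layout."""
    root = tmp_path / "data"
    iface = sp.generate_phantom_dataset(str(root), 3, sp.PhantomConfig(), seed=5)
    return iface


def random_mask(rng, shape, n_classes):
    return rng.integers(0, n_classes, size=shape).astype(np.int32)
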