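import numpy as np
import pytest

from stvgp.io_preprocess import Slice
from stvgp.synthetic import SynthConfig, make_stack


@pytest.fixture(scope="session")
def small_stack():
    """Compact layered stack shared by read-only tests."""
    cfg = SynthConfig(n_slices=2, spots_per_slice=120, n_genes=60, seed=11,
                      rotation_deg=0.0)
    return make_stack(cfg)


def make_labeled_slice(coords, labels, z=0.0, name="s", n_genes=5, seed=0):
    rng = np.random.default_rng(seed)
    coords = np.asarray(coords, dtype=float)
    return Slice(
        expr=rng.random((len(coords), n_genes)),
        coords=coords,
        genes=[f"g{i}" for i in range(n_genes)],
        labels=np.asarray(labels),
        z=z,
        name=name,
    )
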