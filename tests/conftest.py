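import numpy as np
import pytest

import cenkd as ck


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """Small easy synthetic dataset (noise 0.1) with an 80/20 split."""
    root = tmp_path_factory.mktemp("tiny_ds")
    spec = ck.SynthSpec(classes=6, per_class=20, image_size=32, noise=0.1, seed=7)
    manifest = ck.synthesize_dataset(spec, root)
    return ck.split_dataset(manifest, train_fraction=0.8, seed=7)


@pytest.fixture(scope="session")
def tiny_arrays(tiny_dataset):
    from cenkd.data import load_arrays

    return load_arrays(tiny_dataset, "train"), load_arrays(tiny_dataset, "validation")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
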