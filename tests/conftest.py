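import numpy as np
import pytest

import ensemblediff as ed


@pytest.fixture(scope="session")
def toy_spec():
    """Small, fast variant of the synthetic study conditions for unit tests."""
    return ed.ToyEnsembleSpec(n_frames_per_variant=150, seed=7)


@pytest.fixture(scope="session")
def toy_data(toy_spec):
    dataset, flags = ed.generate_toy_ensembles(toy_spec)
    return ed.align_to_reference(dataset), flags


@pytest.fixture(scope="session")
def toy_region(toy_data):
    dataset, _ = toy_data
    return ed.split_region(dataset, ed.synthetic.DEFAULT_TARGET_RESIDUE, 1.0)


@pytest.fixture(scope="session")
def tiny_model():
    """An untrained split model on random data, for structural checks."""
    rng = np.random.default_rng(0)
    n_atoms = 8
    x = rng.normal(size=(40, 3 * n_atoms))
    transform = ed.fit_whitening(x)
    region = ed.RegionSplit(np.array([0, 1, 2]), np.arange(3, 8), 0, 1.0)
    spec = ed.ArchitectureSpec.for_split(region, 4, seed=3)
    params = ed.build_model(spec, transform, region=region)
    return params, x
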