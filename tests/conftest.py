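import pytest

import npek


@pytest.fixture(scope="session")
def toy_set():
    return npek.toy_fixture()


@pytest.fixture(scope="session")
def separable_set():
    """Noise-free chain-length-separable synthetic dataset."""
    return npek.generate(npek.SyntheticSpec.separable(n_background=150, n_positive=25, seed=11))


@pytest.fixture(scope="session")
def separable_matrix(separable_set):
    fm, y = npek.build_cluster_matrix(separable_set.molecules, separable_set.labels("b"))
    return fm, y


@pytest.fixture(scope="session")
def motif_set():
    spec = npek.SyntheticSpec.motif_only(seed=7)
    return spec, npek.generate(spec)
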