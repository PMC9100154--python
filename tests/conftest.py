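import pytest

from celltax.synthetic import generate_dataset
from celltax.training import build_patch_dataset, crossval_split


@pytest.fixture(scope="session")
def small_manifest(tmp_path_factory):
    """A 5-image-per-class synthetic dataset shared across the suite."""
    out = tmp_path_factory.mktemp("dataset")
    return generate_dataset(5, out, seed=11, n_cells_range=(6, 10),
                            n_debris_range=(2, 4))


@pytest.fixture(scope="session")
def patch_dataset(small_manifest):
    return build_patch_dataset(small_manifest)


@pytest.fixture(scope="session")
def folds(small_manifest):
    return crossval_split(small_manifest, k=5, seed=11)
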