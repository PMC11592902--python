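import numpy as np
import pytest

from cytorl.data import PreprocConfig, SplitSpec, stratified_split
from cytorl.synthetic import SyntheticClassSpec, generate_dataset


def numerical_gradient(f, x, eps=1e-6):
    """Central finite differences of scalar-valued f with respect to x."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        x0 = x[i].copy()
        x[i] = x0 + eps
        fp = f()
        x[i] = x0 - eps
        fm = f()
        x[i] = x0
        g[i] = (fp - fm) / (2 * eps)
    return g


@pytest.fixture(scope="session")
def separable_specs():
    """Two well-separated classes (disjoint nucleus-fraction ranges)."""
    return [
        SyntheticClassSpec(0, 100, (0.08, 0.20), 4.0, 0.5, "normal", "normal"),
        SyntheticClassSpec(1, 100, (0.30, 0.50), 4.0, 0.5, "abnormal",
                           "abnormal"),
    ]


@pytest.fixture(scope="session")
def separable_tree(tmp_path_factory, separable_specs):
    root = tmp_path_factory.mktemp("separable")
    manifest = generate_dataset(separable_specs, seed=5, size=(64, 64),
                                out_dir=root / "data", overwrite=True)
    return manifest


@pytest.fixture(scope="session")
def separable_splits(separable_tree):
    return stratified_split(separable_tree, SplitSpec(seed=5))


@pytest.fixture(scope="session")
def tiny_preproc():
    return PreprocConfig(target_size=(32, 32), grayscale=True)
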