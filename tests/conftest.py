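import numpy as np
import pytest
from hypothesis import settings

from orchard3d import TreeSpec, build_scene, build_tree

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_tree_spec() -> TreeSpec:
    return TreeSpec(n_branches=8, point_density=3000.0, prunable_fraction=0.4, seed=7)


@pytest.fixture(scope="session")
def small_tree(small_tree_spec):
    return build_tree(small_tree_spec)


@pytest.fixture(scope="session")
def small_scene(small_tree):
    return build_scene(small_tree, seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform-ish random rotation from a QR decomposition."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1.0
    return Q
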