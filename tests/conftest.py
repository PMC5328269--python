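import numpy as np
import pytest

import annealboost as ab
from annealboost.synthetic import _abstract_stumps


def random_ising(n: int, seed: int, density: float = 1.0) -> ab.IsingProblem:
    """Dense random Ising instance with Gaussian fields and couplings."""
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n, 1)
    J = rng.normal(size=len(iu))
    if density < 1.0:
        J *= rng.random(len(iu)) < density
    keep = J != 0
    return ab.IsingProblem(
        n=n,
        h=rng.normal(size=n),
        edges=np.column_stack([iu, ju])[keep],
        couplings=J[keep],
    )


def random_ensemble(n: int, t: int, seed: int) -> tuple[ab.WeakEnsemble, np.ndarray]:
    """Random +/-1/N output matrix and labels (no planted structure)."""
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1, 1], size=(n, t)).astype(np.int8)
    y = rng.choice([-1, 1], size=t)
    return ab.WeakEnsemble(_abstract_stumps(n), signs), y


@pytest.fixture(scope="session")
def small_scene() -> ab.RasterScene:
    """A 128x128 labeled synthetic scene shared across tests."""
    return ab.generate_scene(ab.SceneSpec(height=128, width=128, seed=42))


@pytest.fixture(scope="session")
def small_table(small_scene) -> ab.FeatureTable:
    return ab.extract_feature_table(small_scene)
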