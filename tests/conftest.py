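import numpy as np
import pytest

from chardir import ExpressionMatrix, TwoClassDesign


def make_two_class(p, n_control, n_perturbed, seed=0, shift=None):
    """Random expression matrix with an optional per-gene mean shift."""
    rng = np.random.default_rng(seed)
    values = rng.normal(size=(p, n_control + n_perturbed))
    if shift is not None:
        values[:, n_control:] += np.asarray(shift)[:, None]
    gene_ids = [f"g{i:04d}" for i in range(p)]
    ctrl = [f"c{j}" for j in range(n_control)]
    pert = [f"t{j}" for j in range(n_perturbed)]
    X = ExpressionMatrix(values, gene_ids, ctrl + pert)
    return X, TwoClassDesign(ctrl, pert)


@pytest.fixture
def small_matrix():
    """10 genes x 6 samples (3 + 3), fixed seed."""
    return make_two_class(10, 3, 3, seed=42)


@pytest.fixture
def medium_matrix():
    """50 genes x 8 samples (4 + 4) with a mild shift on the first 5 genes."""
    shift = np.zeros(50)
    shift[:5] = 1.5
    return make_two_class(50, 4, 4, seed=7, shift=shift)
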