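import numpy as np
import pandas as pd
import pytest

from msrfr.model import Hyperparameters, ModelParameters


def random_instance(seed, K=2, D=6, T=8, N=10, Rs=2, Rk=(2, 2), lam=(0.3, 0.2, 0.4, 0.1)):
    """A small random multitask problem plus parameters at matching ranks."""
    rng = np.random.default_rng(seed)
    Xs = [rng.standard_normal((N, D)) for _ in range(K)]
    Ys = [rng.standard_normal((N, T)) for _ in range(K)]
    params = ModelParameters(
        rng.standard_normal((D, Rs)),
        [rng.standard_normal((D, r)) for r in Rk],
        rng.standard_normal((Rs, T)),
        [rng.standard_normal((r, T)) for r in Rk],
    )
    return (Xs, Ys), params, Hyperparameters(*lam)


@pytest.fixture
def small_instance():
    return random_instance(0)


def make_expression_frame(values, samples=None, features=None):
    values = np.asarray(values, dtype=float)
    samples = samples or [f"s{i}" for i in range(values.shape[0])]
    features = features or [f"f{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=samples, columns=features)
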