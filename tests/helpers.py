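import numpy as np


def random_instance(seed, n_max=8, f_max=5, k_max=2, n_classes=2):
    """A random small graph + model for oracle-equivalence checks."""
    from ggat import default_model_config, init_params

    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, n_max + 1))
    f = int(rng.integers(1, f_max + 1))
    k = int(rng.integers(1, k_max + 1))
    A = (rng.random((n, n)) < 0.5).astype(float)
    A = np.maximum(A, A.T)
    np.fill_diagonal(A, 1.0)
    X = rng.normal(size=(n, f))
    config = default_model_config(n_classes, hidden=3, heads=k, n_layers=3)
    params = init_params(config, f, seed=seed)
    return X, A, params, config
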