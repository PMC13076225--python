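import numpy as np


def random_symmetric_map(n, rng, density=1.0):
    """Random symmetric count matrix with positive entries."""
    m = rng.poisson(5.0 * density, size=(n, n)).astype(float)
    m = np.triu(m)
    return m + np.triu(m, 1).T
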