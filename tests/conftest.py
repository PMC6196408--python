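import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def make_piecewise(rng, n, n_jumps=4, jump_scale=1.5, noise=0.3):
    """Random piecewise-constant signal plus Gaussian noise."""
    levels = rng.normal(scale=jump_scale, size=n_jumps + 1)
    bounds = np.sort(rng.choice(np.arange(1, n), size=min(n_jumps, n - 1),
                                replace=False)) if n > 1 else []
    f = np.empty(n)
    prev = 0
    for li, b in enumerate(list(bounds) + [n]):
        f[prev:b] = levels[li]
        prev = b
    return f + rng.normal(scale=noise, size=n)
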