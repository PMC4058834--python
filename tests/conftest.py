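import numpy as np
import pytest

import fuzzymrf as fm


@pytest.fixture(scope="session")
def default_phantom():
    """One default phantom (seed 0): (ct, suv, truth)."""
    return fm.generate_phantom(fm.default_spec(0))


@pytest.fixture(scope="session")
def petct_result(default_phantom):
    """Full-pipeline petct segmentation of the default phantom."""
    ct, suv, _ = default_phantom
    return fm.segment(ct, suv, fm.OptimConfig(alpha=1e-3))


@pytest.fixture
def small_volume():
    rng = np.random.default_rng(7)
    return fm.Volume(data=rng.normal(size=(4, 4, 2)), spacing=(1.0, 1.5, 3.0))


def random_fields(seed: int, shape) -> fm.LikelihoodFields:
    """Random evidence fields bounded away from zero (no log-floor kinks)."""
    rng = np.random.default_rng(seed)
    return fm.LikelihoodFields(
        A=rng.uniform(0.1, 2.0, shape),
        B=rng.uniform(0.1, 2.0, shape),
        spacing=(1.0, 1.0, 1.0),
    )


def coordinate_grid_search(fields, cfg, step=0.05, max_sweeps=100):
    """Independent optimizer oracle: coordinate-wise exhaustive search over a
    membership grid, swept to stationarity."""
    grid = np.round(np.arange(0.0, 1.0 + step / 2, step), 10)
    x = np.full(fields.shape, 0.5)
    for _ in range(max_sweeps):
        prev = x.copy()
        for idx in np.ndindex(x.shape):
            vals = []
            for v in grid:
                x[idx] = v
                vals.append(fm.energy(x, fields, cfg))
            x[idx] = grid[int(np.argmax(vals))]
        if np.array_equal(prev, x):
            break
    return x, fm.energy(x, fields, cfg)
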