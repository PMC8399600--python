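import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from nirtpc import SpectraSet, WavenumberGrid

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


def make_set(A, concentrations=None, roles="calibration", groups=None, grid=None):
    """Build a SpectraSet around an absorbance matrix with minimal metadata."""
    A = np.asarray(A, dtype=float)
    n, p = A.shape
    if grid is None:
        grid = WavenumberGrid(np.arange(10000.0, 10000.0 - 8 * p, -8.0))
    if concentrations is None:
        concentrations = np.linspace(0, 100, n)
    if groups is None:
        groups = [f"s{i}" for i in range(n)]
    roles = [roles] * n if isinstance(roles, str) else roles
    meta = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "concentration": concentrations,
            "replicate_group": groups,
            "role": roles,
        }
    )
    return SpectraSet(grid, A, meta)


@pytest.fixture
def small_set():
    """3 samples x 5 wavenumbers with simple integer absorbances."""
    return make_set(np.arange(15.0).reshape(3, 5) / 10.0, concentrations=[0.0, 50.0, 100.0])


@pytest.fixture
def random_set():
    rng = np.random.default_rng(7)
    return make_set(rng.normal(1.0, 0.2, size=(5, 20)))
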