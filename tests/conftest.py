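import numpy as np
import pytest

import tabimpute as ti
from tabimpute.tabular_io import CATEGORICAL, CONTINUOUS, Dataset


@pytest.fixture(scope="session")
def suite():
    return ti.standard_suite()


def make_dataset(values, mask=None, col_types=None, cat_levels=None, names=None):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.isnan(values)
    if col_types is None:
        col_types = [CONTINUOUS] * values.shape[1]
    if names is None:
        names = [f"x{j}" for j in range(values.shape[1])]
    return Dataset(values.copy(), np.asarray(mask, bool), names, list(col_types), cat_levels)


@pytest.fixture
def small_mixed():
    """10x4 table: three continuous columns, one 3-level categorical, with a
    few missing cells in every column."""
    rng = np.random.default_rng(7)
    values = rng.standard_normal((10, 4))
    values[:, 3] = rng.integers(0, 3, size=10)
    mask = np.zeros((10, 4), bool)
    mask[[0, 3], 0] = True
    mask[[1], 1] = True
    mask[[2, 5], 2] = True
    mask[[4, 9], 3] = True
    values[mask] = np.nan
    return Dataset(
        values,
        mask,
        ["a", "b", "c", "grade"],
        [CONTINUOUS, CONTINUOUS, CONTINUOUS, CATEGORICAL],
        [None, None, None, ["g0", "g1", "g2"]],  # sorted labels round-trip codes
    )
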