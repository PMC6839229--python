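import numpy as np
import pandas as pd
import pytest

from rulomics.datasets import toy_expression_matrix


@pytest.fixture
def toy_continuous() -> pd.DataFrame:
    return toy_expression_matrix()


@pytest.fixture
def toy_binary(toy_continuous) -> pd.DataFrame:
    return toy_continuous.astype(int)


@pytest.fixture
def random_binary_matrix():
    """Factory: seeded random 0/1 matrix with labelled rows/columns."""

    def make(seed: int, m: int = 20, n: int = 8, p: float = 0.4) -> pd.DataFrame:
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            (rng.random((m, n)) < p).astype(int),
            index=[f"s{i}" for i in range(m)],
            columns=[f"g{j:02d}" for j in range(n)],
        )

    return make


@pytest.fixture
def random_matrix_pair():
    """Factory: seeded continuous matrix plus an aligned random binarization."""

    def make(seed: int, m: int = 30, n: int = 8) -> tuple[pd.DataFrame, pd.DataFrame]:
        rng = np.random.default_rng(seed)
        idx = [f"s{i}" for i in range(m)]
        cols = [f"g{j:02d}" for j in range(n)]
        M = pd.DataFrame(rng.standard_normal((m, n)), index=idx, columns=cols)
        B = pd.DataFrame(
            (rng.random((m, n)) < 0.5).astype(int), index=idx, columns=cols
        )
        return M, B

    return make
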