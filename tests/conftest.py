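import numpy as np
import pytest

from petalscreen import ExpressionMatrix, OrganScheme

ORGANS = (
    "sepal",
    "dorsal_petal",
    "lateral_petal",
    "ventral_petal",
    "stamen",
    "carpel",
    "leaf",
    "root",
)


@pytest.fixture
def scheme() -> OrganScheme:
    return OrganScheme()


@pytest.fixture
def random_matrix_factory():
    """Random 8-organ RPKM matrices from a seeded generator."""

    def make(n_genes: int = 20, seed: int = 0, scale: float = 10.0) -> ExpressionMatrix:
        rng = np.random.default_rng(seed)
        values = scale * rng.gamma(2.0, 1.0, size=(n_genes, len(ORGANS)))
        return ExpressionMatrix(
            [f"g{i}" for i in range(n_genes)], list(ORGANS), values
        )

    return make


def matrix_from_rows(rows: dict[str, list[float]], organs=ORGANS) -> ExpressionMatrix:
    return ExpressionMatrix(
        list(rows), list(organs), np.array(list(rows.values()), dtype=float)
    )
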