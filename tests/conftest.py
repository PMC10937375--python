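import numpy as np
import pytest

from pdskit import ExpressionMatrix, GeneSetCollection


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_matrix(values, gene_prefix="g", sample_prefix="s"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        gene_ids=[f"{gene_prefix}{i + 1}" for i in range(values.shape[0])],
        sample_ids=[f"{sample_prefix}{j + 1}" for j in range(values.shape[1])],
        values=values,
    )


def make_collection(sets: dict[str, list[str]]):
    return GeneSetCollection(set_names=list(sets), members={k: list(v) for k, v in sets.items()})


@pytest.fixture
def toy_matrix():
    # 5 genes x 3 samples, strictly ordered in sample 1
    return make_matrix(
        [
            [5.0, 1.0, 2.0],
            [4.0, 2.0, 2.0],
            [3.0, 3.0, 2.0],
            [2.0, 4.0, 2.0],
            [1.0, 5.0, 2.0],
        ]
    )


@pytest.fixture
def toy_sets():
    return make_collection({"TOP": ["g1", "g2"], "BOTTOM": ["g4", "g5"]})
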