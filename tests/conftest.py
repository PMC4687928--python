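import numpy as np
import pandas as pd
import pytest

from tspec import ClassificationParams, ExpressionMatrix

#: Discrete FPKM grid spanning undetected to highly expressed; adjacent
#: levels differ by at least 2x so fold comparisons are unambiguous.
FPKM_GRID = np.array([0.0, 0.5, 1.0, 3.0, 20.0, 100.0])


@pytest.fixture
def params():
    return ClassificationParams()


@pytest.fixture
def rng():
    return np.random.default_rng(20344)


def random_profile(rng, n_tissues, target="bladder", grid=FPKM_GRID):
    """Random per-tissue FPKM profile over the discrete grid."""
    names = [target] + [f"t{i:02d}" for i in range(1, n_tissues)]
    return pd.Series(rng.choice(grid, size=n_tissues), index=names)


@pytest.fixture
def small_matrix():
    """3 genes x 4 samples over two tissues (two replicates each)."""
    values = pd.DataFrame(
        {
            "s1": [10.0, 0.0, 2.0],
            "s2": [30.0, 0.0, 4.0],
            "s3": [1.0, 5.0, 2.0],
            "s4": [3.0, 7.0, 2.0],
        },
        index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
    )
    tissue_map = {"s1": "bladder", "s2": "bladder", "s3": "testis", "s4": "testis"}
    return ExpressionMatrix(values=values, sample_tissue=tissue_map)
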