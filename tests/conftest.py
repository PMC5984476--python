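import numpy as np
import pytest

from gsabench import (
    ExpressionDataset,
    GeneSet,
    GeneSetCollection,
    null_iid_normal,
    random_collection,
)


@pytest.fixture
def tiny_ds():
    """6 genes x 6 samples, 3 cases / 3 controls, fixed values."""
    rng = np.random.default_rng(42)
    values = rng.normal(size=(6, 6))
    return ExpressionDataset(
        values,
        [f"G{i}" for i in range(6)],
        [f"S{j}" for j in range(6)],
        [1, 1, 1, 0, 0, 0],
    )


@pytest.fixture
def iid_ds():
    """Null dataset: 200 iid standard-normal genes, 10 + 10 samples."""
    return null_iid_normal(200, 10, 10, rng=7)


@pytest.fixture
def small_collection(iid_ds):
    return random_collection(iid_ds.gene_ids, n_sets=10, size_range=(5, 30), rng=11)


@pytest.fixture
def pair_sets():
    a = GeneSet("A", "na", ("g1", "g2", "g3", "g4"))
    b = GeneSet("B", "na", ("g3", "g4", "g5"))
    return a, b


@pytest.fixture
def gmt_file(tmp_path):
    path = tmp_path / "sets.gmt"
    path.write_text(
        "SETA\tna\tG1\tG2\tG3\n"
        "SETB\tdesc\tG2\tG4\n"
        "SETC\tna\tG5\tG6\tG7\tG8\n"
    )
    return path
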