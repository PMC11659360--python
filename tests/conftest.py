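import numpy as np
import pandas as pd
import pytest

from coexmap import make_expression_dataset


def build_dataset(counts_a, counts_b, library_size=None, clusters=None,
                  class_label=None, neurotransmitter=None):
    """Tiny two-gene expression dataset from plain lists."""
    counts_a = np.asarray(counts_a, dtype=np.int64)
    counts_b = np.asarray(counts_b, dtype=np.int64)
    n = counts_a.size
    if library_size is None:
        library_size = np.full(n, 10_000, dtype=np.int64)
    if clusters is None:
        clusters = ["c0"] * n
    if class_label is None:
        class_label = ["neuron"] * n
    if neurotransmitter is None:
        neurotransmitter = ["Glut"] * n
    obs = pd.DataFrame(
        {
            "cluster_id": clusters,
            "class_label": class_label,
            "neurotransmitter": neurotransmitter,
            "library_size": np.asarray(library_size, dtype=np.int64),
        },
        index=pd.Index([f"cell{i}" for i in range(n)], name="cell_id"),
    )
    return make_expression_dataset(
        np.column_stack([counts_a, counts_b]), ["Ghsr", "Cnr1"], obs
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
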