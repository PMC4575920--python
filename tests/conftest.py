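import numpy as np
import pandas as pd
import pytest

from sigforest.counts import CountMatrix


def make_count_matrix(counts, pair_classes=None):
    """CountMatrix from a genes x samples array; samples come in
    (tumor, normal) column pairs P01T, P01N, P02T, ..."""
    counts = np.asarray(counts)
    n_pairs = counts.shape[1] // 2
    assert counts.shape[1] == 2 * n_pairs
    rows = []
    for i in range(n_pairs):
        pair = f"P{i + 1:02d}"
        cls = pair_classes[i] if pair_classes else "A"
        rows.append({"sample_id": f"{pair}T", "pair_id": pair,
                     "condition": "tumor", "class": cls})
        rows.append({"sample_id": f"{pair}N", "pair_id": pair,
                     "condition": "normal", "class": cls})
    sheet = pd.DataFrame(rows).set_index("sample_id")
    genes = [f"g{i + 1}" for i in range(counts.shape[0])]
    return CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=sheet.index),
        samples=sheet,
    )


@pytest.fixture
def small_cm():
    """3 genes x 2 pairs with hand-pickable integer counts."""
    return make_count_matrix([[10, 5, 20, 10],
                              [0, 0, 0, 0],
                              [4, 2, 8, 4]])


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
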