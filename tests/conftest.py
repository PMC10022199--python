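import numpy as np
import pandas as pd
import pytest

from longitree.matrix import CellMetadata, MutationMatrix


def make_metadata(counts: dict[str, int]) -> CellMetadata:
    cells, sample_of = [], {}
    for s, n in counts.items():
        for i in range(1, n + 1):
            c = f"{s}_c{i}"
            cells.append(c)
            sample_of[c] = s
    return CellMetadata(cells=cells, sample_of=sample_of,
                        sample_order=list(counts))


def make_matrix(values, counts: dict[str, int],
                variants: list[str] | None = None) -> MutationMatrix:
    """Build a MutationMatrix from a nested list (NaN encodes NA)."""
    vals = np.asarray(values, dtype=float)
    meta = make_metadata(counts)
    assert vals.shape[0] == meta.n_cells
    if variants is None:
        variants = [f"chr1:{100 + j}:A:T" for j in range(vals.shape[1])]
    data = pd.DataFrame(vals, index=pd.Index(meta.cells, name="cell_id"),
                        columns=variants)
    return MutationMatrix(data=data, metadata=meta)


@pytest.fixture
def two_sample_metadata() -> CellMetadata:
    return make_metadata({"T1": 2, "T2": 2})
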