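import numpy as np
import pandas as pd
import pytest

from distage.datamodel import CellExpressionDataset


@pytest.fixture
def tiny_dataset() -> CellExpressionDataset:
    """Six cells, three genes, three samples with ages 1/2/3 and annotations."""
    expression = np.array(
        [
            [0.0, 5.0, 1.0],
            [1.0, 5.5, 1.2],
            [2.0, 4.5, 0.9],
            [3.0, 5.2, 1.1],
            [4.0, 4.8, 1.0],
            [5.0, 5.1, 0.8],
        ]
    )
    meta = pd.DataFrame(
        {"age": [1.0, 2.0, 3.0], "sex": ["male", "male", "female"]},
        index=pd.Index(["s1", "s2", "s3"], name="sample_id"),
    )
    cells = pd.DataFrame(
        {
            "sex_cell": ["male"] * 4 + ["female"] * 2,
            "cell_type": ["granulocyte", "B cell", "granulocyte", "B cell",
                          "granulocyte", "granulocyte"],
        }
    )
    return CellExpressionDataset(
        expression=expression,
        gene_ids=["g1", "g2", "g3"],
        cell_sample_ids=np.array(["s1", "s1", "s2", "s2", "s3", "s3"], dtype=object),
        sample_metadata=meta,
        cell_annotations=cells,
    )


@pytest.fixture
def small_simulation():
    """A fast three-pattern simulated dataset shared across tests."""
    from distage.simulation import default_config, simulate_dataset

    cfg = default_config(
        n_genes=12,
        fraction_monotonic=1 / 3,
        fraction_nonmonotonic=1 / 3,
        samples_per_age=4,
        cells_per_sample=120,
        seed=42,
    )
    return simulate_dataset(cfg)
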