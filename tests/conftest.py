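import numpy as np
import pytest

from onegene import ExpressionDataset, SimulationConfig, generate


@pytest.fixture
def tiny_dataset() -> ExpressionDataset:
    """3 genes x 4 samples; gene 1 separates the classes perfectly."""
    values = np.array([
        [5.0, 5.1, 4.9, 5.2],
        [1.0, 2.0, 8.0, 9.0],
        [3.0, 7.0, 2.0, 6.0],
    ])
    return ExpressionDataset(
        gene_ids=["gA", "gB", "gC"],
        sample_ids=["s1", "s2", "s3", "s4"],
        values=values,
        labels=np.array(["A", "A", "B", "B"], dtype=object),
    )


@pytest.fixture
def planted_dataset():
    """100 genes, one planted at a 5-SD shift, 20 samples per class."""
    config = SimulationConfig(n1=20, n2=20, n_genes=100, n_informative=1,
                              effect_sizes=(5.0,), seed=42)
    return generate(config)


def make_dataset(values, labels, gene_ids=None, sample_ids=None):
    values = np.asarray(values, dtype=float)
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(values.shape[0])]
    if sample_ids is None:
        sample_ids = [f"s{j}" for j in range(values.shape[1])]
    return ExpressionDataset(gene_ids, sample_ids, values,
                             np.asarray(labels, dtype=object))
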