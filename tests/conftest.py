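import numpy as np
import pandas as pd
import pytest

from perturbkit import PerturbationDataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_dataset():
    """3 cells x 2 genes, two perturbations + control, with a 2-d rep."""
    return PerturbationDataset(
        matrix=np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]),
        obs=pd.DataFrame(
            {"perturbation": ["A", "B", "A"]}, index=["c1", "c2", "c3"]
        ),
        feature_ids=["g1", "g2"],
        representations={"pca": np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])},
    )


def make_gaussian_dataset(
    rng, group_means, n_cells=50, n_genes=20, sd=1.0, control="control"
):
    """Gaussian groups with given per-group mean offsets; first is control."""
    labels = []
    rows = []
    names = [control] + [f"g{i}" for i in range(1, len(group_means))]
    for name, mu in zip(names, group_means):
        block = rng.normal(loc=mu, scale=sd, size=(n_cells, n_genes))
        rows.append(block)
        labels += [name] * n_cells
    X = np.vstack(rows)
    obs = pd.DataFrame(
        {"perturbation": labels}, index=[f"c{i}" for i in range(len(labels))]
    )
    return PerturbationDataset(
        matrix=X, obs=obs, feature_ids=[f"gene{j}" for j in range(n_genes)]
    )
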