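import numpy as np
import pandas as pd
import pytest

from tregstrat import SyntheticOmicsConfig, generate_multiomics, preprocess_dataset


def small_omics_config(seed: int = 7, **overrides) -> SyntheticOmicsConfig:
    """Compact study conditions used by unit tests (fast, still 4 layers)."""
    kwargs = dict(
        n_samples=120,
        n_clusters=3,
        layer_specs=[
            ("mRNA", 120, "nonneg_continuous"),
            ("miRNA", 40, "nonneg_continuous"),
            ("methylation", 60, "unit_interval"),
            ("protein", 30, "continuous"),
        ],
        cluster_sep=3.0,
        frac_informative=0.2,
        treg_effect=2.0,
        seed=seed,
    )
    kwargs.update(overrides)
    return SyntheticOmicsConfig(**kwargs)


@pytest.fixture(scope="session")
def small_dataset():
    dataset, truth = generate_multiomics(small_omics_config())
    return dataset, truth


@pytest.fixture(scope="session")
def small_joint(small_dataset):
    dataset, truth = small_dataset
    with pytest.warns(UserWarning):  # retain counts exceed synthetic widths
        _, joint = preprocess_dataset(dataset)
    return joint, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_layer_frame(rng, n=10, p=6, missing=0):
    """Plain random samples-by-features frame, optionally with NaNs."""
    X = rng.standard_normal((n, p))
    if missing:
        idx = rng.choice(n * p, size=missing, replace=False)
        X.flat[idx] = np.nan
    return pd.DataFrame(
        X,
        index=[f"S{i}" for i in range(n)],
        columns=[f"F{j}" for j in range(p)],
    )
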