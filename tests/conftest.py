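import numpy as np
import pandas as pd
import pytest

from coexnet.simulate import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down planted design used by the recovery tests: three modules
    big enough to survive the default minimum size plus background noise."""
    return SyntheticConfig(
        module_sizes=(80, 60, 50),
        n_background=310,
        n_samples_per_group=8,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def paired_perturbed_dataset():
    """Two 200-gene modules, one destroyed in the HS condition."""
    config = SyntheticConfig(
        module_sizes=(200, 200),
        n_background=600,
        loading_range=(0.5, 0.9),
        noise_sd=1.0,
        perturbations={"M2": "destroy"},
        seed=7,
    )
    expr, samples, truth = generate_dataset(config)
    ctrl = expr[samples.loc[samples["group"] == "CTRL", "sample_id"]]
    hs = expr[samples.loc[samples["group"] == "HS", "sample_id"]]
    return config, expr, samples, truth, ctrl, hs


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_expr(rng, n_genes, n_samples, prefix="g"):
    return pd.DataFrame(
        rng.standard_normal((n_genes, n_samples)),
        index=[f"{prefix}{i}" for i in range(n_genes)],
        columns=[f"s{i}" for i in range(n_samples)],
    )
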