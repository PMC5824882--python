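import dataclasses

import numpy as np
import pytest

import fibrosort as fs


@pytest.fixture(scope="session")
def small_cfg() -> fs.GeneratorConfig:
    """Small but non-degenerate generator config shared across tests."""
    return fs.GeneratorConfig(
        n_genes=400,
        n_signature_genes_per_subset=20,
        n_donors_ra=3,
        n_donors_oa=2,
        cells_per_donor=40,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_bulk(small_cfg):
    return fs.generate_bulk_cohort(small_cfg)


@pytest.fixture(scope="session")
def small_cells(small_cfg):
    cfg = dataclasses.replace(small_cfg, n_donors_ra=2, n_donors_oa=2)
    return fs.generate_single_cells(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_matrix(rng, n_genes=12, n_samples=5, scale="tpm") -> fs.ExpressionMatrix:
    values = rng.gamma(2.0, 10.0, size=(n_genes, n_samples))
    if scale == "log2":
        values = np.log2(values + 1.0)
    return fs.ExpressionMatrix(
        [f"g{i}" for i in range(n_genes)],
        [f"s{j}" for j in range(n_samples)],
        values,
        scale,
    )
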