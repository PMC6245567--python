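import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import rxscape as rx


@pytest.fixture(scope="session")
def small_population():
    """200 providers x 40 drugs, 3 specialties, 2 regions, default censoring."""
    cfg = rx.default_config(
        n_providers=200, n_drugs=40, n_classes=8, n_specialties=3, n_regions=2,
        seed=42,
    )
    matrix, annotations, class_map, truth = rx.generate_population(cfg)
    return cfg, matrix, annotations, class_map, truth


@pytest.fixture(scope="session")
def trimmed_population(small_population):
    cfg, matrix, annotations, class_map, truth = small_population
    trimmed, _ = rx.drop_empty(matrix)
    return cfg, trimmed, annotations.loc[trimmed.providers], class_map, truth


def toy_matrix(dense, censor_threshold=0, providers=None):
    """Build a ClaimsMatrix from a dense array with auto-generated indexes."""
    dense = np.asarray(dense)
    n, m = dense.shape
    if providers is None:
        providers = [f"1{i:09d}" for i in range(n)]
    drugs = rx.containers.make_drug_index(
        [f"B{j}" for j in range(m)], [f"g{j}" for j in range(m)]
    )
    return rx.ClaimsMatrix(
        sp.csr_matrix(dense), pd.Index(providers, name="npi"), drugs,
        censor_threshold=censor_threshold,
    )


@pytest.fixture
def toy():
    return toy_matrix
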