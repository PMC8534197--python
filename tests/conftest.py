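import numpy as np
import pandas as pd
import pytest

import thyroclass as tc
from thyroclass import expression


@pytest.fixture(scope="session")
def default_config() -> tc.CohortConfig:
    return tc.CohortConfig(seed=1)


@pytest.fixture(scope="session")
def cohort(default_config):
    """Default synthetic cohort: (CountMatrix, CohortTruth)."""
    return tc.generate_counts(default_config)


@pytest.fixture(scope="session")
def cohort_log_matrix(cohort) -> pd.DataFrame:
    counts, _ = cohort
    return expression.build_expression_matrix(counts, log=True).values


@pytest.fixture(scope="session")
def cohort_fpm_matrix(cohort) -> pd.DataFrame:
    counts, _ = cohort
    return expression.build_expression_matrix(counts, log=False).values


@pytest.fixture(scope="session")
def reference(default_config):
    """Labelled synthetic reference matrix (26 BRAF V600E + 61 RAS), FPM scale."""
    return tc.generate_reference_matrix(default_config)


@pytest.fixture(scope="session")
def signatures(default_config):
    from thyroclass.synthetic import signature_genes

    sig = signature_genes(default_config)
    return {name: tc.GeneSignature(name, genes) for name, genes in sig.items()}


def make_counts(values, genes=None, samples=None, biotype="protein_coding", cosmic="none"):
    """Small CountMatrix helper for unit tests."""
    arr = np.asarray(values)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    counts = pd.DataFrame(arr, index=genes, columns=samples)
    if isinstance(biotype, str):
        biotype = [biotype] * len(genes)
    if isinstance(cosmic, str):
        cosmic = [cosmic] * len(genes)
    meta = pd.DataFrame({"biotype": biotype, "cosmic_role": cosmic}, index=genes)
    return expression.CountMatrix(counts=counts, gene_meta=meta)
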