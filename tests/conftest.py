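import numpy as np
import pandas as pd
import pytest

from msbr import methylation
from msbr.synthetic import (
    generate_cohort,
    generate_pathways,
    luminal_a_preset,
)


@pytest.fixture(scope="session")
def cohort_a():
    """Luminal-A-like preset cohort: 40 tumors (k=2), 20 normals, 500 probes."""
    spec = luminal_a_preset(seed=11)
    beta, ann, truth = generate_cohort(spec)
    return beta, ann, truth


@pytest.fixture(scope="session")
def pathways_a(cohort_a):
    _, ann, truth = cohort_a
    return generate_pathways(truth, universe=set(ann.table["gene_symbol"]), seed=11)


@pytest.fixture(scope="session")
def imputed_a(cohort_a):
    beta, ann, _ = cohort_a
    m = beta.subset_probes(methylation.promoter_probes(ann))
    m = methylation.filter_missingness(m)
    return methylation.knn_impute(m)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def group_ids(beta, group):
    return [s for s, g in beta.sample_groups.items() if g == group]
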