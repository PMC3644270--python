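import numpy as np
import pandas as pd
import pytest

import enrichcord as ec


@pytest.fixture
def toy_study() -> ec.ExpressionStudy:
    """3 genes x 4 samples, one platform/site, 2 replicates per condition."""
    values = pd.DataFrame(
        {
            "s1": [1.0, 5.0, 8.0],
            "s2": [2.0, 5.5, 8.1],
            "s3": [3.0, 4.0, 7.9],
            "s4": [4.0, 4.5, 8.2],
        },
        index=["G1", "G2", "G3"],
    )
    design = pd.DataFrame(
        {
            "platform": ["AFX"] * 4,
            "site": ["1"] * 4,
            "condition": ["A", "A", "B", "B"],
            "replicate": [1, 2, 1, 2],
        },
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
    )
    return ec.ExpressionStudy(values, design)


@pytest.fixture(scope="session")
def desk_study():
    """The default desk-scale simulated study (seed 1), shared across tests."""
    return ec.generate_study(ec.StudyDesign.desk_default(seed=1))


@pytest.fixture(scope="session")
def desk_stats(desk_study):
    studies, _sets, _truth = desk_study
    common = ec.common_genes(studies)
    return ec.compute_gene_statistics(studies[0], site="1", genes=common, seed=7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)
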