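import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from g2o import ExpressionMatrix, SyntheticConfig, generate_paired_cohorts

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def toy_matrix():
    """3 genes x 4 samples with simple integer values."""
    data = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0], [5.0, 5.0, 5.0, 5.0]],
        index=["GA", "GB", "GC"],
        columns=["S1", "S2", "S3", "S4"],
    )
    return ExpressionMatrix(data, "rnaseq")


@pytest.fixture
def toy_calls():
    """Six-row somatic call table exercising every acceptance rule."""
    return pd.DataFrame(
        {
            "sample_id": ["S1", "S2", "S3", "S1", "S4", "S2"],
            "gene": ["GA", "GA", "GA", "GB", "GB", "GC"],
            "judgment": ["KEEP", "REJECT", "KEEP", "KEEP", "KEEP", "KEEP"],
            "alt_reads": [4, 50, 3, 10, 8, 4],
            "coverage": [20, 200, 25, 19, 40, 20],
            "function_class": [
                "non-synonymous coding",
                "stop gain",
                "splice site",
                "intron",
                "synonymous coding",
                "non-synonymous coding",
            ],
        }
    )


@pytest.fixture(scope="session")
def small_synthetic():
    """A reduced paired-cohort dataset shared across tests (fixed seed)."""
    cfg = SyntheticConfig(
        n_ngs=120, n_chip=250, n_genes=300, n_up=20, n_down=20, seed=7
    )
    return generate_paired_cohorts(cfg)


@pytest.fixture(scope="session")
def default_synthetic():
    """One dataset at the standard study conditions (fixed seed)."""
    return generate_paired_cohorts(SyntheticConfig(seed=11))
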