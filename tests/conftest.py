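import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from rhizoeval import FeatureTable, StudyDesign, default_fungal_model, generate_counts

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def small_table():
    """3 taxa × 4 samples with hand-checkable counts."""
    df = pd.DataFrame(
        {
            "s1": [5, 3, 2],
            "s2": [0, 6, 4],
            "s3": [1, 1, 8],
            "s4": [2, 2, 2],
        },
        index=pd.Index(["tA", "tB", "tC"], name="taxon_id"),
    )
    return FeatureTable(df)


@pytest.fixture(scope="session")
def default_fungal_study():
    """The default 4×5 fungal community at seed 1, shared across tests."""
    design = StudyDesign(seed=1)
    return generate_counts(design, default_fungal_model())


def random_table(rng, n_taxa=12, n_samples=8, max_count=50) -> FeatureTable:
    counts = rng.integers(0, max_count, size=(n_taxa, n_samples))
    df = pd.DataFrame(
        counts,
        index=pd.Index([f"t{i}" for i in range(n_taxa)], name="taxon_id"),
        columns=[f"s{j}" for j in range(n_samples)],
    )
    return FeatureTable(df)
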