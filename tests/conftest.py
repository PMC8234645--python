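import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

hypothesis_settings.register_profile("no-db", database=None, derandomize=True)
hypothesis_settings.load_profile("no-db")

from atlas_scrub import (
    CleaningConfig,
    DefectSpec,
    ExpressionMatrix,
    SampleSpec,
    SimConfig,
    mtgea_accounting_fixture,
    scaled_sum_threshold,
    simulate_matrix,
)


@pytest.fixture(scope="session")
def accounting_fixture():
    """The 716-column fixture with the full planted-defect accounting."""
    return mtgea_accounting_fixture(seed=1)


@pytest.fixture(scope="session")
def accounting_config():
    return CleaningConfig(sum_min=scaled_sum_threshold(5000))


@pytest.fixture(scope="session")
def healthy_small():
    """Defect-free 1000-probe atlas: 10 three-replicate samples."""
    config = SimConfig(
        samples=[SampleSpec(f"Tissue_{i:02d}", 3) for i in range(10)],
        n_probes=1000,
    )
    return simulate_matrix(config, DefectSpec(), seed=11)


@pytest.fixture()
def tiny_matrix():
    """Hand-sized 3-probe x 4-column matrix for exact-value checks."""
    return ExpressionMatrix(
        probe_ids=["p1", "p2", "p3"],
        column_labels=["A_1", "A_2", "B_1", "B_2"],
        values=np.array(
            [
                [1.0, 2.0, 3.0, 4.0],
                [5.0, 6.0, 7.0, 8.0],
                [9.0, 10.0, 11.0, 12.5],
            ]
        ),
    )
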