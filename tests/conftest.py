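import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import HealthCheck, settings

from glomscape.io import SpatialCellTable
from glomscape.synthetic import CohortConfig, generate_cohort, generate_reference

settings.register_profile(
    "ci", derandomize=True, max_examples=30,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("ci")


def make_table(n_cells=20, n_genes=5, seed=0, **cell_cols) -> SpatialCellTable:
    """Small hand-checkable table with random counts."""
    rng = np.random.default_rng(seed)
    cells = pd.DataFrame({
        "x_um": rng.uniform(0, 100, n_cells),
        "y_um": rng.uniform(0, 100, n_cells),
        "slide_id": "slide1",
        "sample_id": "s1",
        "condition": "control",
    }, index=pd.Index([f"c{i}" for i in range(n_cells)], name="cell_id"))
    for k, v in cell_cols.items():
        cells[k] = v
    counts = sp.csr_matrix(rng.poisson(1.0, size=(n_cells, n_genes)))
    genes = [f"G{i}" for i in range(n_genes)]
    return SpatialCellTable(cells, counts, genes)


@pytest.fixture(scope="session")
def small_cohort():
    """Two control + two anti-GBM samples; shared by integration tests."""
    cfg = CohortConfig(n_samples_per_condition={"control": 2, "anti-GBM": 2})
    table, truth = generate_cohort(cfg, seed=7)
    return cfg, table, truth


@pytest.fixture(scope="session")
def default_cohort():
    """The default four-condition cohort (5 samples each)."""
    cfg = CohortConfig()
    table, truth = generate_cohort(cfg, seed=3)
    return cfg, table, truth


@pytest.fixture(scope="session")
def reference_model(small_cohort):
    """Classifier trained on the synthetic reference."""
    from glomscape.celltyping import CellTypeClassifier

    cfg, _, _ = small_cohort
    counts, labels, genes = generate_reference(cfg, n_per_type=200, seed=11)
    model = CellTypeClassifier(random_state=0).fit(counts, labels, genes=genes)
    return model
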