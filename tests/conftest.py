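import warnings

import numpy as np
import pandas as pd
import pytest

from plaquescape.config import AnalysisThresholds, Genotype, GENOTYPE_ORDER
from plaquescape.preprocess import qc_filter_cells
from plaquescape.simulate import SimConfig, simulate_cohort
from plaquescape.validation import null_config, uniform_densities

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def thresholds():
    return AnalysisThresholds()


@pytest.fixture(scope="session")
def small_null_cohort():
    """Null cohort (no planted effects), 4 genotypes x 2 batches, small."""
    cfg = null_config(42, cell_type_densities=uniform_densities(0.15e-4))
    design = [(g, f"b{i + 1}") for i in range(2) for g in GENOTYPE_ORDER]
    ds, truth = simulate_cohort(cfg, design, seed=42)
    return ds, truth


@pytest.fixture(scope="session")
def small_null_qc(small_null_cohort):
    ds, truth = small_null_cohort
    cells, counts = qc_filter_cells(ds.cells, ds.counts)
    return ds, cells, counts, truth


@pytest.fixture()
def tiny_tables():
    """Three cells, two genes: the smallest loadable dataset."""
    cells = pd.DataFrame({
        "cell_id": ["c1", "c2", "c3"],
        "x": [0.0, 10.0, 20.0],
        "y": [0.0, 5.0, 10.0],
        "volume": [500.0, 700.0, 900.0],
        "total_transcripts": [3, 7, 11],
        "sample_id": ["s0"] * 3,
        "batch_id": ["b1"] * 3,
        "genotype": ["WT", "5xFAD", "Trem2R47H;5xFAD"],
    })
    counts = pd.DataFrame(
        np.array([[1, 2], [3, 4], [5, 6]]),
        index=["c1", "c2", "c3"], columns=["Gfap", "Itgax"],
    )
    return cells, counts
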