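import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose tests/_oracles.py

from fibrosysmap.datatypes import ExpressionStudy
from fibrosysmap.synthetic import SyntheticConfig


@pytest.fixture
def small_config():
    """Down-scaled cohort for fast unit tests."""
    return SyntheticConfig(
        seed=7, n_genes=300, n_tfs=8, n_mirnas=10, n_samples_per_group=6,
        n_planted_degs=20, n_pathways=8, planted_crosstalk_pairs=1,
        n_planted_ffls=3, n_planted_demirs=6, n_background_reads=2000,
    )


@pytest.fixture
def microarray_study():
    """Tiny deterministic microarray study: 6 genes, 4+4 samples, two genes
    strongly shifted in the case group."""
    rng = np.random.default_rng(42)
    genes = [f"g{i}" for i in range(6)]
    samples = [f"ipf{i}" for i in range(4)] + [f"ctl{i}" for i in range(4)]
    values = rng.normal(8.0, 0.2, (6, 8))
    values[0, :4] += 3.0   # up in IPF
    values[1, :4] -= 3.0   # down in IPF
    labels = pd.Series(["IPF"] * 4 + ["control"] * 4, index=samples)
    return ExpressionStudy(
        study_id="ma1", platform="microarray",
        matrix=pd.DataFrame(values, index=genes, columns=samples),
        units="log_intensity", sample_labels=labels,
    )


def deg_table(study_id, calls):
    """Build a DEG call table from {gene: direction}."""
    return pd.DataFrame({
        "gene": list(calls),
        "study_id": study_id,
        "direction": list(calls.values()),
        "log2fc": [1.5 if d == "up" else -1.5 for d in calls.values()],
        "p_value": 0.01,
    })


@pytest.fixture
def make_deg_table():
    return deg_table
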