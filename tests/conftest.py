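import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import HealthCheck, settings

import dfurescue as dr

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cohort():
    """Default simulated cohort (seed 1), QC-filtered and normalized."""
    expr, manifest = dr.simulate_cohort(seed=1)
    lr_pairs = expr.lr_pairs
    filtered, report = dr.filter_cells(expr)
    norm = dr.normalize(filtered)
    norm.lr_pairs = lr_pairs
    return {"raw": expr, "expr": norm, "manifest": manifest, "qc_report": report}


@pytest.fixture(scope="session")
def null_cohort():
    expr, manifest = dr.simulate_cohort(dr.SimConfig.null(), seed=1)
    filtered, _ = dr.filter_cells(expr)
    return {"expr": dr.normalize(filtered), "manifest": manifest}


@pytest.fixture(scope="session")
def cohort_de(cohort):
    """Both DE contrasts on the default cohort."""
    expr = cohort["expr"]
    return {
        "unhealing": dr.de_all_cell_types(expr, "DFUNH", "DS"),
        "healing": dr.de_all_cell_types(expr, "DFUH", "DFUNH"),
    }


def small_expression(counts, groups=None, cell_types=None, samples=None, tissue="skin"):
    """Build a LabeledExpression from a dense array and simple metadata."""
    counts = np.asarray(counts)
    n_genes, n_cells = counts.shape
    genes = np.asarray([f"g{i + 1}" for i in range(n_genes)], dtype=object)
    cells = np.asarray([f"c{i + 1}" for i in range(n_cells)], dtype=object)
    meta = pd.DataFrame(
        {
            "sample_id": samples if samples is not None else ["s1"] * n_cells,
            "group": groups if groups is not None else ["DS"] * n_cells,
            "tissue": tissue,
            "cell_type": cell_types if cell_types is not None else ["Fibro"] * n_cells,
        },
        index=cells,
    )
    return dr.LabeledExpression(
        counts=sp.csr_matrix(counts), gene_ids=genes, cell_ids=cells, meta=meta
    )


@pytest.fixture
def make_expr():
    return small_expression
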