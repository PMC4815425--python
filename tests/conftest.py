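import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import metadeg as md
from metadeg.synthgen import SimParams

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


def make_study(matrix_values, gene_ids, sheet_rows):
    """Small annotated study from literal values.

    ``sheet_rows`` is a list of (sample_id, study_id, arm, part, method).
    """
    sheet = pd.DataFrame(
        sheet_rows, columns=["sample_id", "study_id", "arm", "part", "method"]
    )
    matrix = pd.DataFrame(
        np.asarray(matrix_values, dtype=float),
        index=pd.Index(gene_ids, name="gene_id"),
        columns=sheet["sample_id"],
    )
    return md.annotate(md.ExpressionStudy(matrix), sheet)


@pytest.fixture(scope="session")
def two_arm_study():
    """One contrast, 2 genes, 2 replicates per arm (hand-checkable)."""
    return make_study(
        [[4.0, 6.0, 2.0, 2.0], [3.0, 3.0, 3.0, 3.0]],
        ["gA", "gB"],
        [
            ("t1", "s1", "treated", "root", "water_withholding"),
            ("t2", "s1", "treated", "root", "water_withholding"),
            ("c1", "s1", "control", "root", "water_withholding"),
            ("c2", "s1", "control", "root", "water_withholding"),
        ],
    )


@pytest.fixture(scope="session")
def sim_study():
    """Moderate simulated collection shared across tests (read-only)."""
    params = SimParams(n_genes=250, seed=42, part_effect_sd=0.3)
    study, sheet, truth = md.simulate_collection(params)
    return study, sheet, truth
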