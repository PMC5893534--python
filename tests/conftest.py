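import numpy as np
import pandas as pd
import pytest

from pathfabric import CohortConfig, generate_cohort, normalize_median
from pathfabric.cohort import ExpressionCohort


@pytest.fixture(scope="session")
def sim():
    """Moderate synthetic cohort with planted effects and co-expressed blocks."""
    cfg = CohortConfig(
        n_genes=1200,
        seed=11,
        n_coexpressed_blocks=3,
        block_size=8,
        make_probes=True,
        probes_per_gene=(1, 3),
    )
    cohort, truth = generate_cohort(cfg)
    return cfg, cohort, truth


@pytest.fixture(scope="session")
def sim_norm(sim):
    cfg, cohort, truth = sim
    return cfg, normalize_median(cohort), truth


def _make_cohort(values: dict, conditions=("BNS", "BYS"), sex="male", n_rep=4):
    """Tiny hand-built cohort: values maps gene -> list of per-sample values
    ordered (cond1 rep1..repN, cond2 rep1..repN, ...)."""
    rows = []
    cols = []
    for cond in conditions:
        for rep in range(1, n_rep + 1):
            sid = f"{sex[0].upper()}_{cond}_{rep}"
            cols.append(sid)
            rows.append(
                {"sample_id": sid, "sex": sex, "condition": cond, "replica": rep}
            )
    df = pd.DataFrame.from_dict(values, orient="index", columns=cols)
    return ExpressionCohort(values=df, samples=pd.DataFrame(rows))


@pytest.fixture
def make_cohort():
    return _make_cohort


@pytest.fixture
def tiny_cohort():
    """3 genes x 8 male samples (BNS, BYS x 4 replicas): one flat gene,
    one cleanly up in BYS, one cleanly down."""
    return _make_cohort(
        {
            "flat": [10, 10, 10, 10, 10, 10, 10, 10],
            "up": [1.0, 1.1, 0.9, 1.0, 2.0, 2.2, 1.8, 2.0],
            "down": [4.0, 4.4, 3.6, 4.0, 1.0, 1.1, 0.9, 1.0],
        }
    )
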