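import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import gxenull as gx

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_analysis_cohort(config: gx.SimConfig) -> pd.DataFrame:
    """Generate a cohort and attach the GRS + deciles, ready for model fits."""
    return gx.build_analysis_cohort(config)


@pytest.fixture(scope="session")
def small_bundle() -> gx.CohortBundle:
    return gx.generate_cohort(gx.SimConfig(n_individuals=800, n_variants=12, seed=11))


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    return make_analysis_cohort(gx.SimConfig(n_individuals=2000, n_variants=15, seed=5))


@pytest.fixture()
def toy_weights() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "variant_id": ["rs1", "rs2", "rs3"],
            "effect_allele": ["A", "C", "G"],
            "other_allele": ["G", "T", "A"],
            "weight": [0.1, 0.2, 0.3],
            "eaf": [0.3, 0.4, 0.5],
        }
    )


def ols_oracle(X: np.ndarray, y: np.ndarray):
    """Independent closed-form OLS: beta = (X'X)^-1 X'y, classical SEs.

    Deliberately a direct normal-equations solve, not shared with the
    implementation under test.
    """
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    sigma2 = resid @ resid / df
    se = np.sqrt(np.diag(sigma2 * np.linalg.inv(XtX)))
    return beta, se, df
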