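import warnings

import numpy as np
import pandas as pd
import pytest

from refluxmr import SimConfig, simulate_cohort

# statsmodels emits convergence chatter on tiny fixtures; keep output clean
warnings.filterwarnings("ignore", message=".*Maximum Likelihood optimization.*")


@pytest.fixture(scope="session")
def small_cohort():
    """5 000-individual cohort with a real causal effect and imperfect
    coding; shared across read-only tests."""
    cfg = SimConfig(
        n_individuals=5_000,
        n_variants=20,
        causal_beta=float(np.log(1.2)),
        code_sensitivity=0.85,
        code_specificity=0.995,
        n_relative_pairs=100,
        seed=11,
    )
    return cfg, simulate_cohort(cfg)


@pytest.fixture()
def summary_fixture():
    """5-variant summary-statistic table with known fields."""
    rng = np.random.default_rng(42)
    return pd.DataFrame(
        {
            "variant_id": [f"v{i}" for i in range(5)],
            "beta_x": rng.normal(0.1, 0.03, 5),
            "se_x": np.full(5, 0.008),
            "beta_y": rng.normal(0.03, 0.015, 5),
            "se_y": rng.uniform(0.006, 0.02, 5),
        }
    )
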