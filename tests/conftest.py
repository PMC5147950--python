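import numpy as np
import pandas as pd
import pytest

import fpscore as f
from fpscore.vocab import count_columns


def make_cohort(marginal_rows, region="neck"):
    """Cohort from a list of (N_A, N_B, N_C, N_D) tuples, counts in one region."""
    ids = [f"T{i + 1}" for i in range(len(marginal_rows))]
    marg = pd.DataFrame(
        marginal_rows, index=ids, columns=["N_A", "N_B", "N_C", "N_D"]
    )
    return f.Cohort.from_marginals(marg, region=region)


@pytest.fixture
def small_cohort():
    """Three turtles spanning all three severity levels."""
    counts = pd.DataFrame(0, index=["T1", "T2", "T3"], columns=count_columns())
    counts.loc["T1", "left_forelimb_A"] = 3
    counts.loc["T1", "neck_B"] = 2
    counts.loc["T2", "right_forelimb_B"] = 50  # FPI 50 -> moderate
    counts.loc["T3", "left_hindlimb_C"] = 4
    counts.loc["T3", "carapace_D"] = 2  # FPI 160 -> severe
    return f.Cohort(counts)


@pytest.fixture(scope="session")
def synthetic_cohort():
    """Default-condition cohort: 214 turtles, TTA on 27, subjective on 52."""
    return f.generate_cohort(f.default_config(seed=123))


@pytest.fixture(scope="session")
def noiseless_tta_cohort():
    """Cohort whose 27-turtle TTA subset is exactly the counts-based linear
    predictor (no noise); the fixture seed gives the subset variation in all
    four size classes so every coefficient is identifiable."""
    return f.generate_cohort(
        f.default_config(seed=7, tta_noise_sd=0.0), with_subjective=False
    )
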