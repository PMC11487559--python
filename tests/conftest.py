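import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import tcellstates as tcs

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_bundle() -> tcs.CohortBundle:
    """A compact synthetic cohort (6000 genes, 16 samples, effect 3)."""
    return tcs.generate_cohort(n_genes=6000, n_samples=16, seed=11)


@pytest.fixture(scope="session")
def small_result(small_bundle) -> tcs.TCSSResult:
    return tcs.score_samples(
        small_bundle.expression,
        small_bundle.marker_sets,
        small_bundle.reference,
        small_bundle.housekeeping,
        seed=7,
    )


@pytest.fixture
def toy_matrix() -> tcs.ExpressionMatrix:
    data = pd.DataFrame(
        {"s1": [1.0, 3.0, 5.0], "s2": [2.0, 4.0, 6.0]},
        index=["g1", "g2", "g3"],
    )
    return tcs.ExpressionMatrix(data, stage="tpm")


def brute_force_u_fraction(marker_vals, background_vals) -> float:
    """Independent oracle: marker-vs-background pairwise win fraction,
    ties counted one half."""
    wins = 0.0
    for mv in marker_vals:
        for bv in background_vals:
            if mv > bv:
                wins += 1.0
            elif mv == bv:
                wins += 0.5
    return wins / (len(marker_vals) * len(background_vals))
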