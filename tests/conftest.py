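import numpy as np
import pandas as pd
import pytest

import hazardcut as hc
from hazardcut.survival import EndpointSpec


@pytest.fixture(scope="session")
def default_cohort():
    """Default synthetic cohort at the emulated study size."""
    return hc.simulate_cohort(hc.SimulationConfig(n_patients=197, seed=42))


@pytest.fixture(scope="session")
def two_group_frame():
    """Simple two-covariate survival frame with a known generating model."""
    rng = np.random.default_rng(1)
    n = 300
    x = rng.standard_normal(n)
    g = rng.integers(0, 2, n).astype(float)
    t = rng.exponential(1 / (0.1 * np.exp(0.7 * x + 0.5 * g)))
    c = rng.exponential(8, n)
    return pd.DataFrame(
        {"time": np.minimum(t, c), "event": (t <= c).astype(int), "x": x, "g": g}
    )


def single_marker_config(seed, beta, n=200, covariate_effects=None, clinical=None):
    """One-marker cohort generator used by the cutoff and profile tests."""
    effects = {"m": beta} if beta else {}
    if covariate_effects:
        effects.update(covariate_effects)
    return hc.SimulationConfig(
        n_patients=n,
        marker_names=("m",),
        target_corr=np.eye(1),
        clinical_spec=clinical or {},
        true_effects={"LRC": effects} if effects else {},
        true_cutoffs={"m": 0.5},
        baseline_hazard={"LRC": 0.06, "DM": 0.0},
        death_rate=0.05,
        censor_rate=0.15,
        seed=seed,
    )


@pytest.fixture(scope="session")
def marker_endpoint_spec():
    return EndpointSpec(name="LRC", covariates=())
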