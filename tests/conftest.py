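import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import pentamsea as pm

settings.register_profile(
    "default", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def ctx():
    return pm.LibraryContext()


@pytest.fixture(scope="session")
def library(ctx):
    return pm.enumerate_library(ctx)


@pytest.fixture(scope="session")
def all_sets(ctx):
    return pm.generate_all_layers(ctx=ctx)


@pytest.fixture(scope="session")
def filtered_sets(all_sets):
    kept, _ = pm.filter_sets(all_sets)
    return kept


@pytest.fixture(scope="session")
def default_sim(ctx):
    """One synthetic screen with the default planted panel."""
    return pm.generate_psi_matrix(pm.SyntheticSpec(seed=3), ctx)


@pytest.fixture(scope="session")
def toy_ranking():
    """A 10-item ranking with distinct mixed-sign metric values."""
    import pandas as pd
    values = np.array([5.0, 3.5, 2.0, 1.0, 0.5, -0.5, -1.5, -2.0, -3.0, -4.5])
    return pd.Series(values, index=[f"g{i}" for i in range(10)])


def brute_force_es(metric, hit_mask, p=1.0):
    """Independent O(N) running-sum walk oracle for the enrichment score."""
    metric = np.asarray(metric, dtype=float)
    hit_mask = np.asarray(hit_mask, dtype=bool)
    N, m = len(metric), int(hit_mask.sum())
    w = np.abs(metric) ** p if p != 0 else np.ones(N)
    nr = w[hit_mask].sum()
    if nr == 0:
        w, nr = np.ones(N), float(m)
    walk = np.empty(N)
    rs = 0.0
    for i in range(N):
        rs += w[i] / nr if hit_mask[i] else -1.0 / (N - m)
        walk[i] = rs
    hi, lo = walk.max(), walk.min()
    if hi >= -lo - 1e-12:   # ties prefer the positive extreme
        return float(hi), int(np.argmax(walk)) + 1, walk
    return float(lo), int(np.argmin(walk)) + 1, walk
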