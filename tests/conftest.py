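import itertools

import numpy as np
import pandas as pd
import pytest

from cgiscreen.simulate import SimulationConfig, generate_methylation_cohort


# ---------------------------------------------------------------------------
# independent oracles (brute force / enumeration), shared across test modules


def bh_stepup_oracle(p):
    """Literal Benjamini–Hochberg step-up: sort ascending, scale p(k) by m/k,
    take the running minimum from the largest p downward, cap at 1."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj_sorted = np.empty(m)
    running = np.inf
    for k in range(m, 0, -1):
        running = min(running, p[order[k - 1]] * m / k)
        adj_sorted[k - 1] = min(running, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def paired_t_oracle(d):
    """Closed form: t = mean/(sd/sqrt(n)), two-sided p from Student t."""
    import scipy.stats as st

    d = np.asarray(d, dtype=float)
    n = d.size
    t = d.mean() / (d.std(ddof=1) / np.sqrt(n))
    return t, 2 * st.t.sf(abs(t), n - 1)


def mann_whitney_oracle(x, y):
    """Exact two-sided p by enumerating all group assignments of the pooled
    ranks; assumes no ties."""
    pooled = np.concatenate([x, y])
    n = len(x)
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    u_all = np.array(
        [
            ranks[list(comb)].sum() - n * (n + 1) / 2
            for comb in itertools.combinations(range(len(pooled)), n)
        ]
    )
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    p = 2 * min((u_all <= u_obs).mean(), (u_all >= u_obs).mean())
    return u_obs, min(p, 1.0)


def wilcoxon_oracle(d):
    """Exact two-sided p by enumerating all 2^n sign assignments of the
    ranked |d|; assumes no zeros and no tied magnitudes."""
    d = np.asarray(d, dtype=float)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    n = len(d)
    w_all = np.array(
        [
            sum(r for r, s in zip(ranks, signs) if s)
            for signs in itertools.product([0, 1], repeat=n)
        ]
    )
    w_obs = ranks[d > 0].sum()
    p = 2 * min((w_all <= w_obs).mean(), (w_all >= w_obs).mean())
    return min(p, 1.0)


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_regions=120, n_pairs=12, seed=20240101)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_methylation_cohort(small_config)


@pytest.fixture()
def tiny_beta():
    """3 probes × 2 samples with one missing value."""
    return pd.DataFrame(
        {"S1": [0.1, 0.5, np.nan], "S2": [0.2, 0.6, 0.9]},
        index=pd.Index(["cg01", "cg02", "cg03"], name="probe_id"),
    )
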