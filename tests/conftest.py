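"""Shared fixtures: small synthetic cohorts and voxel datasets."""
import numpy as np
import pytest

from tractdx import SimulationConfig, simulate_cohort_table, simulate_voxel_dataset


@pytest.fixture(scope="session")
def null_cohort():
    """103 healthy controls, no patients, no injury."""
    cfg = SimulationConfig(n_patients=0, injured_fraction=0.0)
    table, _ = simulate_cohort_table(cfg, seed=101)
    return table


@pytest.fixture(scope="session")
def injured_cohort():
    """103 controls + 12 patients each losing 4 SD of FA in 4 tracts."""
    cfg = SimulationConfig(n_patients=12, effect_size=4.0, n_injured_rois=4)
    table, truth = simulate_cohort_table(cfg, seed=202)
    return table, truth


@pytest.fixture(scope="session")
def voxel_dataset():
    """Small voxel-level study: 12 controls + 3 patients on a 32^3 grid."""
    cfg = SimulationConfig(n_controls=12, n_patients=3, effect_size=4.0,
                           n_injured_rois=3, voxel_noise_sd=0.02)
    return simulate_voxel_dataset(cfg, seed=303)


# ---------------------------------------------------------------------------
# independent oracles (used by several test modules)
# ---------------------------------------------------------------------------

def bh_stepup_oracle(p):
    """Brute-force Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for k in range(m - 1, -1, -1):
        running = min(running, p[order[k]] * m / (k + 1))
        adj[order[k]] = running
    return adj


def icc_oracle(Y, model):
    """ICC from explicitly summed ANOVA tables (independent of the package)."""
    Y = np.asarray(Y, dtype=float)
    n, k = Y.shape
    grand = Y.sum() / (n * k)
    ss_subj = 0.0
    for i in range(n):
        ss_subj += k * (Y[i].sum() / k - grand) ** 2
    ss_col = 0.0
    for j in range(k):
        ss_col += n * (Y[:, j].sum() / n - grand) ** 2
    ss_tot = 0.0
    for i in range(n):
        for j in range(k):
            ss_tot += (Y[i, j] - grand) ** 2
    msb = ss_subj / (n - 1)
    msc = ss_col / (k - 1)
    mse = (ss_tot - ss_subj - ss_col) / ((n - 1) * (k - 1))
    if model == "consistency":
        return (msb - mse) / (msb + (k - 1) * mse)
    return (msb - mse) / (msb + (k - 1) * mse + k * (msc - mse) / n)
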