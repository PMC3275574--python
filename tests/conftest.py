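import numpy as np
import pytest

from tfanca import FitOptions, generate_dataset


@pytest.fixture
def small_dataset():
    """Small, fully active network: 6 TFs, 60 genes, 12 conditions, sigma=0.1."""
    return generate_dataset(n_tfs=6, n_genes=60, targets_per_tf=10,
                            n_conditions=12, n_perturbed=0, effect_size=0.0,
                            noise_sd=0.1, activity_sd=1.0, seed=7)


@pytest.fixture
def quick_opts():
    return FitOptions(tol=1e-6, max_iter=300, n_restarts=0, seed=0)


def align_correlations(fit, truth):
    """Per-TF |Pearson r| between recovered and true activity rows."""
    out = {}
    for i, t in enumerate(fit.tf_ids):
        j = truth.pattern.tf_ids.index(t)
        out[t] = abs(float(np.corrcoef(fit.P[i], truth.P_true[j])[0, 1]))
    return out


def two_block_tfa(n_tfs=12, n_samples=40, shift=3.0, sd=0.2, n_shifted=6, seed=0):
    """Cohort TFA with a common baseline profile and a shifted sample block."""
    rng = np.random.default_rng(seed)
    base = rng.standard_normal(n_tfs)
    status = np.zeros(n_samples, dtype=int)
    status[n_samples // 2:] = 1
    tfa = base[:, None] + sd * rng.standard_normal((n_tfs, n_samples))
    signs = rng.choice([-1.0, 1.0], n_shifted)
    tfa[:n_shifted, status == 1] += shift * signs[:, None]
    return tfa, status
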