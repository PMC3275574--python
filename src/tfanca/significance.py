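"""Null-network calibration of TF activities and perturbed-TF selection.

The significance of an inferred TFA is judged against activity values obtained
by applying the *same* network structure, with the same fitting options, to
expression rows sampled at random from a background genome pool (~200 random
networks by default).  Each observed TFA is standardized by the robust modified
z-score, 0.6745 * (x - median) / MAD, and converted to a two-tail p-value by
the standard normal tail; the median/MAD pair is used instead of mean/SD so
that a few outlying null fits cannot distort the calibration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .io_preprocess import ConnectivityPattern
from .nca_engine import DecompositionResult, FitOptions, _fit_values, _normalize

logger = logging.getLogger(__name__)

#: consistency constant making MAD estimate the SD of a normal distribution
MAD_CONSISTENCY = 0.6745


@dataclass
class NullDistribution:
    """Per-(TF, condition) null TFA values from random-gene networks."""

    values: np.ndarray  # (n_networks, n_tfs, n_conditions)
    tf_ids: tuple[str, ...]
    condition_ids: tuple[str, ...]
    n_networks: int
    seed: int
    source_pool_id: str = "background_pool"

    def to_frame(self):
        import pandas as pd

        rows = [(d, t, c, self.values[d, i, j])
                for d in range(self.n_networks)
                for i, t in enumerate(self.tf_ids)
                for j, c in enumerate(self.condition_ids)]
        return pd.DataFrame(rows, columns=["network", "TF", "condition", "TFA"])


@dataclass
class SignificanceResult:
    """Modified z-scores and two-tail p-values per (TF, condition) cell."""

    z: np.ndarray
    p: np.ndarray
    tf_ids: tuple[str, ...]
    condition_ids: tuple[str, ...]
    degenerate: np.ndarray  # cells whose null MAD was zero
    tail: str = "normal"

    def to_frame(self, tfa: np.ndarray | None = None, alpha: float = 0.05):
        import pandas as pd

        rows = []
        for i, t in enumerate(self.tf_ids):
            for j, c in enumerate(self.condition_ids):
                rows.append({"TF": t, "condition": c,
                             "TFA": None if tfa is None else tfa[i, j],
                             "z": self.z[i, j], "p": self.p[i, j],
                             "selected": bool(self.p[i, j] < alpha)})
        return pd.DataFrame(rows)


def build_null(pool: np.ndarray, pattern: ConnectivityPattern,
               n_networks: int = 200, seed: int = 0,
               opts: FitOptions | None = None,
               condition_ids: tuple[str, ...] | None = None) -> NullDistribution:
    """TFA null distribution from random-gene networks.

    For each of ``n_networks`` draws, every pattern gene's expression row is
    replaced by a row sampled without replacement (within the draw) from the
    background pool; the pattern is then fitted with identical options and the
    resulting activities collected.
    """
    from .nca_engine import check_identifiability

    opts = opts or FitOptions()
    pool = np.asarray(pool, dtype=float)
    mask = pattern.mask()
    if pool.shape[0] < mask.shape[0]:
        raise ValueError("background pool has fewer genes than the pattern")
    report = check_identifiability(pattern)
    if not report.identifiable:
        raise ValueError(f"pattern not identifiable; failing TFs: {list(report.failing_tfs)}")
    rng = np.random.default_rng(seed)
    n_cond = pool.shape[1]
    values = np.empty((n_networks, mask.shape[1], n_cond))
    for d in range(n_networks):
        idx = rng.choice(pool.shape[0], size=mask.shape[0], replace=False)
        sub = FitOptions(opts.tol, opts.max_iter, opts.n_restarts,
                         seed=int(rng.integers(2**31)))
        A, P, *_ = _fit_values(pool[idx], mask, sub)
        _, P = _normalize(A, P)
        values[d] = P
    if condition_ids is None:
        condition_ids = tuple(f"S{c + 1:03d}" for c in range(n_cond))
    return NullDistribution(values=values, tf_ids=pattern.tf_ids,
                            condition_ids=condition_ids,
                            n_networks=n_networks, seed=seed)


def modified_zscore(x: float, null_values: np.ndarray) -> tuple[float, float]:
    """Robust standardization of ``x`` against a list of null values.

    z = 0.6745 * (x - median) / MAD, p = 2 * (1 - Phi(|z|)).  A zero MAD marks
    a degenerate null: z is signed infinity and p is reported as 0.0 (callers
    should treat such cells via the ``degenerate`` flag, not as evidence).
    """
    null_values = np.asarray(null_values, dtype=float)
    if null_values.size < 10:
        raise ValueError("need at least 10 null values")
    med = float(np.median(null_values))
    mad = float(np.median(np.abs(null_values - med)))
    if mad == 0.0:
        logger.warning("modified_zscore: degenerate null (MAD = 0)")
        z = np.inf if x > med else (-np.inf if x < med else 0.0)
        return z, 0.0 if z != 0.0 else 1.0
    z = MAD_CONSISTENCY * (x - med) / mad
    p = float(2.0 * norm.sf(abs(z)))
    return float(z), min(p, 1.0) if p > 0 else np.nextafter(0, 1)


def significance_scores(tfa: np.ndarray | DecompositionResult,
                        null: NullDistribution,
                        tail: str = "normal",
                        fdr: bool = False) -> SignificanceResult:
    """Score every (TF, condition) cell of an observed TFA matrix.

    ``tail='normal'`` converts the modified z through the standard normal tail
    (the default, a two-tail z-test); ``tail='empirical'`` uses the rank of the
    observation among the centred null values instead.  ``fdr=True`` applies
    Benjamini-Hochberg control across all cells (off by default: perturbed-TF
    selection conventionally uses the raw two-tail p-values).
    """
    if isinstance(tfa, DecompositionResult):
        tfa = tfa.P
    tfa = np.asarray(tfa, dtype=float)
    n_tfs, n_cond = tfa.shape
    if null.values.shape[1:] != (n_tfs, n_cond):
        raise ValueError("null distribution shape does not match the TFA matrix")
    z = np.zeros_like(tfa)
    p = np.ones_like(tfa)
    degenerate = np.zeros(tfa.shape, dtype=bool)
    for i in range(n_tfs):
        for j in range(n_cond):
            cell = null.values[:, i, j]
            z[i, j], p[i, j] = modified_zscore(tfa[i, j], cell)
            med = np.median(cell)
            mad = np.median(np.abs(cell - med))
            if mad == 0.0:
                degenerate[i, j] = True
            elif tail == "empirical":
                k = int(np.sum(np.abs(cell - med) >= abs(tfa[i, j] - med)))
                p[i, j] = (1 + k) / (len(cell) + 1)
    if tail not in ("normal", "empirical"):
        raise ValueError("tail must be 'normal' or 'empirical'")
    if fdr:
        from scipy.stats import false_discovery_control

        p = false_discovery_control(p.ravel(), method="bh").reshape(p.shape)
    return SignificanceResult(z=z, p=p, tf_ids=null.tf_ids,
                              condition_ids=null.condition_ids,
                              degenerate=degenerate, tail=tail)


def select_perturbed_tfs(sig: SignificanceResult, alpha: float = 0.05) -> list[str]:
    """TFs significant (p < alpha) in at least one condition, sorted by min p.

    The default alpha of 0.05 is the conventional two-tail z-test cutoff for
    calling a TFA perturbed.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    min_p = sig.p.min(axis=1)
    chosen = [(min_p[i], t) for i, t in enumerate(sig.tf_ids) if min_p[i] < alpha]
    return [t for _, t in sorted(chosen, key=lambda x: (x[0], x[1]))]
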