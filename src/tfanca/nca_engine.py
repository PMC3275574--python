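"""Constrained bilinear decomposition E ~ A.P under a connectivity zero pattern.

Network component analysis (NCA) models log expression ratios as
``E[g, c] = sum_t A[g, t] * P[t, c]`` where the support of the control-strength
matrix A is fixed by known TF -> gene connectivity and P holds the latent
per-condition TF activities (TFAs).  The decomposition is unique up to a per-TF
scale/sign when the pattern satisfies the structural rank conditions checked by
:func:`check_identifiability`; the fit itself is an alternating least squares
(ALS) in which the P-step is an unconstrained least squares given A and the
A-step solves, per gene, a least squares restricted to that gene's regulators.

The module also implements network trimming: edges whose fitted control
strength is indistinguishable from the strength obtained on random background
genes are removed, iteratively, using a median/MAD modified z-score against a
null built from refits on background-gene expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import structural_rank

from .io_preprocess import ConnectivityPattern, ExpressionRatios

logger = logging.getLogger(__name__)

_RESIDUAL_FLOOR = 1e-14


@dataclass(frozen=True)
class FitOptions:
    """ALS options.

    tol
        stop when the relative Frobenius-residual change drops below this.
    max_iter
        iteration cap per start.
    n_restarts
        number of random on-pattern initializations tried in addition to the
        deterministic SVD-projection start; the best residual wins.
    """

    tol: float = 1e-6
    max_iter: int = 1000
    n_restarts: int = 3
    seed: int = 0


@dataclass
class IdentifiabilityReport:
    identifiable: bool
    failing_tfs: tuple[str, ...]
    rank_details: dict
    warnings: tuple[str, ...] = ()


@dataclass
class DecompositionResult:
    """NCA fit: control strengths A (genes x TFs) and activities P (TFs x conds).

    A is exactly zero off-pattern; each column of A has unit Euclidean norm with
    its largest-magnitude entry positive (scale and sign are absorbed into P).
    """

    A: np.ndarray
    P: np.ndarray
    residual_fro: float
    n_iter: int
    converged: bool
    pattern_used: ConnectivityPattern
    gene_ids: tuple[str, ...]
    tf_ids: tuple[str, ...]
    condition_ids: tuple[str, ...]
    init_residual: float
    residual_path: tuple[float, ...] = field(default=(), repr=False)

    def tfa_frame(self):
        import pandas as pd

        return pd.DataFrame(self.P, index=pd.Index(self.tf_ids, name="TF"),
                            columns=list(self.condition_ids))


# ---------------------------------------------------------------------------
# identifiability

def check_identifiability(pattern: ConnectivityPattern,
                          n_conditions: int | None = None) -> IdentifiabilityReport:
    """Structural-rank test of the NCA uniqueness conditions.

    The decomposition is essentially unique (per-TF scale/sign aside) when
    (i) the pattern supports a generically full-column-rank A, and (ii) for
    every TF t, deleting t's column and the rows of t's targets leaves a
    sub-pattern of structural column rank n_tfs - 1.  Too few conditions
    (n_conditions < n_tfs) is reported as a warning, not a failure, since it
    degrades conditioning rather than structural identifiability of A.
    """
    mask = pattern.mask()
    n_genes, n_tfs = mask.shape
    if n_tfs == 0 or n_genes == 0:
        raise ValueError("empty pattern")
    full_rank = int(structural_rank(csr_matrix(mask)))
    details: dict = {"structural_rank": full_rank, "n_tfs": n_tfs}
    failing: list[str] = []
    if full_rank < n_tfs:
        failing = list(pattern.tf_ids)
        details["reduced_ranks"] = {}
    else:
        reduced: dict[str, int] = {}
        for j, tf in enumerate(pattern.tf_ids):
            rows = ~mask[:, j]
            cols = np.arange(n_tfs) != j
            sub = mask[np.ix_(rows, cols)]
            r = int(structural_rank(csr_matrix(sub))) if sub.size else 0
            reduced[tf] = r
            if r < n_tfs - 1:
                failing.append(tf)
        details["reduced_ranks"] = reduced
    warnings: list[str] = []
    if n_conditions is not None and n_conditions < n_tfs:
        warnings.append(
            f"n_conditions={n_conditions} < n_tfs={n_tfs}: activity matrix cannot "
            "have full row rank; estimates may be poorly conditioned")
    return IdentifiabilityReport(identifiable=not failing,
                                 failing_tfs=tuple(failing),
                                 rank_details=details,
                                 warnings=tuple(warnings))


# ---------------------------------------------------------------------------
# ALS core

def _support_groups(mask: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    """Group gene rows by identical regulator set for batched A-step solves."""
    keys: dict[bytes, list[int]] = {}
    for g in range(mask.shape[0]):
        keys.setdefault(mask[g].tobytes(), []).append(g)
    groups = []
    for key, genes in keys.items():
        support = np.flatnonzero(np.frombuffer(key, dtype=bool))
        if support.size:
            groups.append((np.asarray(genes), support))
    return groups


def _a_step(E: np.ndarray, P: np.ndarray,
            groups: list[tuple[np.ndarray, np.ndarray]],
            shape: tuple[int, int]) -> np.ndarray:
    A = np.zeros(shape)
    for genes, support in groups:
        # solve min ||E[genes] - A[genes, support] @ P[support]||_F
        coef, *_ = np.linalg.lstsq(P[support].T, E[genes].T, rcond=None)
        A[np.ix_(genes, support)] = coef.T
    return A


def _p_step(E: np.ndarray, A: np.ndarray) -> np.ndarray:
    P, *_ = np.linalg.lstsq(A, E, rcond=None)
    return P


def _svd_init(E: np.ndarray, mask: np.ndarray, groups,
              rng: np.random.Generator, ridge: float = 1e-3) -> np.ndarray:
    """Near-deterministic start: project a rank-n_tfs SVD basis onto the
    pattern support with a small ridge (ALS is non-convex; this start is
    usually in the right basin on identifiable instances).  When fewer
    singular directions than TFs exist the remaining activity rows are seeded
    with small noise so no TF starts — and stays — identically zero."""
    n_tfs = mask.shape[1]
    k = min(n_tfs, min(E.shape))
    U, s, Vt = np.linalg.svd(E, full_matrices=False)
    P0 = (s[:k, None] * Vt[:k])
    if k < n_tfs:
        scale = s[k - 1] if k and s[k - 1] > 0 else 1.0
        P0 = np.vstack([P0, 0.1 * scale * rng.standard_normal((n_tfs - k, E.shape[1]))])
    A = np.zeros(mask.shape)
    for genes, support in groups:
        M = P0[support] @ P0[support].T + ridge * np.eye(support.size)
        coef = np.linalg.solve(M, P0[support] @ E[genes].T)
        A[np.ix_(genes, support)] = coef.T
    return A


def _run_als(E: np.ndarray, mask: np.ndarray, A0: np.ndarray,
             tol: float, max_iter: int) -> tuple[np.ndarray, np.ndarray, list[float], int, bool]:
    groups = _support_groups(mask)
    norm_E = float(np.linalg.norm(E))
    A = A0
    P = _p_step(E, A)
    res = [float(np.linalg.norm(E - A @ P))]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        A = _a_step(E, P, groups, mask.shape)
        P = _p_step(E, A)
        r = float(np.linalg.norm(E - A @ P))
        res.append(r)
        prev = res[-2]
        if r <= _RESIDUAL_FLOOR * max(norm_E, 1.0) or prev == 0.0:
            converged = True
            break
        if (prev - r) / prev < tol:
            converged = True
            break
    return A, P, res, it, converged


def _normalize(A: np.ndarray, P: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit-norm A columns, dominant entry positive; scale/sign go into P."""
    A = A.copy()
    P = P.copy()
    for t in range(A.shape[1]):
        norm = np.linalg.norm(A[:, t])
        if norm > 0:
            A[:, t] /= norm
            P[t] *= norm
        imax = int(np.argmax(np.abs(A[:, t])))
        if A[imax, t] < 0:
            A[:, t] = -A[:, t]
            P[t] = -P[t]
    return A, P


def _align(E: ExpressionRatios, pattern: ConnectivityPattern,
           ) -> tuple[np.ndarray, ConnectivityPattern]:
    """Intersect E's genes with the pattern's; drop TFs left without targets."""
    in_E = set(E.gene_ids)
    genes = [g for g in pattern.gene_ids if g in in_E]
    if not genes:
        raise ValueError("no overlap between expression genes and pattern genes")
    ignored = E.n_genes - len(genes)
    if ignored:
        logger.info("nca_decompose: %d expression gene(s) absent from the pattern ignored",
                    ignored)
    kept_genes = set(genes)
    edges = {e for e in pattern.edges if e[0] in kept_genes}
    surviving_tfs = {t for _, t in edges}
    dropped = set(pattern.tf_ids) - surviving_tfs
    if dropped:
        logger.warning("nca_decompose: TF(s) without surviving targets dropped: %s",
                       sorted(dropped))
    aligned = ConnectivityPattern(
        tf_ids=tuple(t for t in pattern.tf_ids if t in surviving_tfs),
        gene_ids=tuple(genes),
        edges=frozenset(edges),
        evidence={e: v for e, v in pattern.evidence.items() if e in edges},
    )
    values = E.reorder_genes(aligned.gene_ids).values
    return values, aligned


def _fit_values(values: np.ndarray, mask: np.ndarray,
                opts: FitOptions) -> tuple[np.ndarray, np.ndarray, list[float], int, bool]:
    """Best-of-starts ALS on a raw matrix; used by the public fit and by the
    null-network machinery (which swaps in background rows positionally)."""
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite expression input")
    rng = np.random.default_rng(opts.seed)
    groups = _support_groups(mask)
    starts = [_svd_init(values, mask, groups, rng)]
    for _ in range(opts.n_restarts):
        A0 = np.where(mask, rng.standard_normal(mask.shape), 0.0)
        starts.append(A0)
    best = None
    for A0 in starts:
        out = _run_als(values, mask, A0, opts.tol, opts.max_iter)
        if best is None or out[2][-1] < best[2][-1]:
            best = out
    return best


def nca_decompose(E: ExpressionRatios, pattern: ConnectivityPattern,
                  opts: FitOptions | None = None) -> DecompositionResult:
    """Fit the constrained decomposition E ~ A.P by alternating least squares.

    Genes present in E but absent from the pattern are ignored (count logged);
    TFs with no surviving target are dropped before fitting.  If the aligned
    pattern is not identifiable a warning is logged and a best-effort fit is
    returned.  The returned A obeys the zero pattern exactly and carries the
    unit-column-norm / dominant-entry-positive convention.
    """
    opts = opts or FitOptions()
    values, aligned = _align(E, pattern)
    report = check_identifiability(aligned, E.n_conditions)
    if not report.identifiable:
        logger.warning("pattern not identifiable (failing TFs: %s); best-effort fit",
                       list(report.failing_tfs))
    mask = aligned.mask()
    fit = _fit_values(values, mask, opts)
    return _package_fit(fit, aligned, E.condition_ids)


def _package_fit(fit, aligned: ConnectivityPattern,
                 condition_ids: tuple[str, ...]) -> DecompositionResult:
    A, P, res, n_iter, converged = fit
    A, P = _normalize(A, P)
    return DecompositionResult(
        A=A, P=P, residual_fro=res[-1], n_iter=n_iter, converged=converged,
        pattern_used=aligned, gene_ids=aligned.gene_ids, tf_ids=aligned.tf_ids,
        condition_ids=condition_ids, init_residual=res[0],
        residual_path=tuple(res))


# ---------------------------------------------------------------------------
# trimming

def edge_strengths(result: DecompositionResult) -> dict[tuple[str, str], float]:
    """Per-edge strength |A[g,t]| * ||P[t,:]||.

    The product is invariant to the per-TF scale/sign indeterminacy, so the
    statistic does not depend on the normalization convention.
    """
    p_norm = np.linalg.norm(result.P, axis=1)
    gi = {g: i for i, g in enumerate(result.gene_ids)}
    ti = {t: j for j, t in enumerate(result.tf_ids)}
    return {(g, t): float(abs(result.A[gi[g], ti[t]]) * p_norm[ti[t]])
            for g, t in result.pattern_used.edges}


def _stable_strengths(values: np.ndarray, P: np.ndarray, mask: np.ndarray,
                      rcond: float = 0.1) -> np.ndarray:
    """(genes x tfs) edge strengths |a| * ||P_t|| from a truncated-SVD
    projection of each gene's profile onto its regulators' activity rows.

    The plain per-gene least squares explodes in sign-cancelling coefficient
    pairs whenever the fitted activity rows are nearly collinear — routine on
    null (random-gene) fits, where the activities are not anchored by real
    structure.  Truncating singular directions below ``rcond`` of the largest
    caps that blow-up while leaving well-conditioned fits exactly at their
    least-squares coefficients; observed and null strengths are always
    computed with the same estimator so the comparison stays fair.
    """
    out = np.zeros(mask.shape)
    for genes, support in _support_groups(mask):
        coef, *_ = np.linalg.lstsq(P[support].T, values[genes].T, rcond=rcond)
        out[np.ix_(genes, support)] = coef.T
    return np.abs(out) * np.linalg.norm(P, axis=1)[None, :]


@dataclass(frozen=True)
class TrimOptions:
    n_null: int = 50
    z_cut: float = 1.0
    max_rounds: int = 5
    seed: int = 0


@dataclass
class TrimResult:
    pattern: ConnectivityPattern
    fit: DecompositionResult
    removed_edges: tuple[tuple[str, str], ...]
    protected_edges: tuple[tuple[str, str], ...]
    n_rounds: int


def _null_strengths(mask: np.ndarray, pool: np.ndarray, n_null: int,
                    opts: FitOptions, rng: np.random.Generator) -> np.ndarray:
    """(n_null, genes, tfs) array of edge strengths from background refits.

    Each draw replaces every pattern gene's expression row by a distinct row
    sampled without replacement from the background pool and refits with
    identical ALS options.
    """
    n_genes = mask.shape[0]
    if pool.shape[0] < n_genes:
        raise ValueError("background pool smaller than the pattern gene count")
    out = np.empty((n_null, *mask.shape))
    for d in range(n_null):
        idx = rng.choice(pool.shape[0], size=n_genes, replace=False)
        sub = FitOptions(opts.tol, opts.max_iter, opts.n_restarts,
                         seed=int(rng.integers(2**31)))
        _, P, *_ = _fit_values(pool[idx], mask, sub)
        out[d] = _stable_strengths(pool[idx], P, mask)
    return out


def _refit_warm(E: ExpressionRatios, pattern: ConnectivityPattern,
                previous: DecompositionResult,
                opts: FitOptions) -> DecompositionResult:
    """Refit after edge removal, warm-starting ALS from the previous solution.

    The previous round's fit is a good solution of a slightly larger problem;
    restarting cold can land in a worse ALS basin, so the warm fit is compared
    against a cold fit and the lower residual wins.
    """
    values, aligned = _align(E, pattern)
    mask = aligned.mask()
    gi = {g: i for i, g in enumerate(previous.gene_ids)}
    ti = {t: j for j, t in enumerate(previous.tf_ids)}
    A0 = np.zeros(mask.shape)
    for i, g in enumerate(aligned.gene_ids):
        for j, t in enumerate(aligned.tf_ids):
            if mask[i, j]:
                A0[i, j] = previous.A[gi[g], ti[t]]
    warm = _run_als(values, mask, A0, opts.tol, opts.max_iter)
    cold = nca_decompose(E, pattern, opts)
    if warm[2][-1] < cold.residual_fro:
        return _package_fit(warm, aligned, E.condition_ids)
    return cold


def trim_network(E: ExpressionRatios, pattern: ConnectivityPattern,
                 pool: np.ndarray, trim_opts: TrimOptions | None = None,
                 fit_opts: FitOptions | None = None) -> TrimResult:
    """Iteratively remove edges whose control strength matches the random-gene null.

    Round structure: fit; build a null distribution of per-edge strengths from
    ``n_null`` background refits; drop every edge whose observed strength has a
    modified z-score below ``z_cut``; refit; stop when nothing is removed or
    ``max_rounds`` is reached.  An edge whose removal would disconnect its TF
    entirely is kept and logged instead.
    """
    from .significance import modified_zscore

    trim_opts = trim_opts or TrimOptions()
    fit_opts = fit_opts or FitOptions()
    if pool is None or np.size(pool) == 0:
        raise ValueError("trim_network requires a background expression pool")
    rng = np.random.default_rng(trim_opts.seed)
    current = pattern
    removed: list[tuple[str, str]] = []
    protected: list[tuple[str, str]] = []
    fit = nca_decompose(E, current, fit_opts)
    rounds = 0
    for rounds in range(1, trim_opts.max_rounds + 1):
        aligned = fit.pattern_used
        mask = aligned.mask()
        values = E.reorder_genes(aligned.gene_ids).values
        obs_mat = _stable_strengths(values, fit.P, mask)
        gi_o = {g: i for i, g in enumerate(aligned.gene_ids)}
        ti_o = {t: j for j, t in enumerate(aligned.tf_ids)}
        obs = {(g, t): obs_mat[gi_o[g], ti_o[t]] for g, t in aligned.edges}
        null = _null_strengths(mask, pool, trim_opts.n_null, fit_opts, rng)
        gi = {g: i for i, g in enumerate(aligned.gene_ids)}
        ti = {t: j for j, t in enumerate(aligned.tf_ids)}
        tf_degree = {t: sum(1 for _, u in aligned.edges if u == t)
                     for t in aligned.tf_ids}
        to_remove: list[tuple[str, str]] = []
        for (g, t), s in obs.items():
            z, _ = modified_zscore(s, null[:, gi[g], ti[t]])
            if z < trim_opts.z_cut:
                if tf_degree[t] - sum(1 for e in to_remove if e[1] == t) <= 1:
                    protected.append((g, t))
                    logger.warning("trim_network: edge (%s, %s) spared — last link of %s",
                                   g, t, t)
                    continue
                to_remove.append((g, t))
        if not to_remove:
            break
        removed.extend(to_remove)
        current = aligned.restrict_edges(aligned.edges - set(to_remove))
        fit = _refit_warm(E, current, fit, fit_opts)
    else:
        rounds = trim_opts.max_rounds
    if trim_opts.max_rounds == 0:
        rounds = 0
    return TrimResult(pattern=fit.pattern_used, fit=fit,
                      removed_edges=tuple(removed),
                      protected_edges=tuple(protected), n_rounds=rounds)


# ---------------------------------------------------------------------------
# result I/O

def write_decomposition(result: DecompositionResult, a_path, p_path,
                        summary_path=None, extra: Mapping | None = None) -> None:
    """TSV of A (gene, TF, CS) on-pattern entries, TSV of P (TF x condition),
    optional JSON fit summary."""
    import json

    import pandas as pd

    gi = {g: i for i, g in enumerate(result.gene_ids)}
    ti = {t: j for j, t in enumerate(result.tf_ids)}
    rows = sorted(result.pattern_used.edges, key=lambda e: (gi[e[0]], ti[e[1]]))
    pd.DataFrame({"gene": [g for g, _ in rows],
                  "TF": [t for _, t in rows],
                  "CS": [result.A[gi[g], ti[t]] for g, t in rows]}
                 ).to_csv(a_path, sep="\t", index=False)
    result.tfa_frame().to_csv(p_path, sep="\t")
    if summary_path is not None:
        summary = {"residual_fro": result.residual_fro,
                   "init_residual": result.init_residual,
                   "n_iter": result.n_iter,
                   "converged": bool(result.converged),
                   "n_tfs": len(result.tf_ids),
                   "n_genes": len(result.gene_ids),
                   "n_conditions": len(result.condition_ids)}
        if extra:
            summary.update(extra)
        with open(summary_path, "w") as fh:
            json.dump(summary, fh, indent=2)
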