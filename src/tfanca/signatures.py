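"""Downstream analytics on inferred TFA matrices.

Samples are clustered with the un-centered correlation (cosine) metric and
complete linkage; cluster membership is tested for association with a binary
functional status (e.g. PTEN positive/negative) by a Pearson chi-squared test
of group 1 against the pooled remaining groups; per-TF differences between
status groups use two-sample t-tests, from which a TFA signature is derived at
a configurable threshold; co-activity structure is summarized by the matrix of
absolute pairwise Pearson correlations with a clustered ordering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import chi2_contingency, ttest_ind

logger = logging.getLogger(__name__)

#: significance marks used in reports (one to three stars)
MARK_THRESHOLDS = (0.05, 0.001, 1e-4)


@dataclass
class ClusterResult:
    """Complete-linkage clustering of samples under the cosine metric."""

    linkage_matrix: np.ndarray
    group_labels: np.ndarray  # 1..k, group 1 = smallest cluster
    k: int
    metric: str = "cosine"
    leaf_order: tuple[int, ...] = ()


def cluster_samples(tfa: np.ndarray, k: int) -> ClusterResult:
    """Agglomerative clustering of sample columns of a TFA matrix.

    Distance between samples x, y is 1 - sum(x_i y_i)/(||x|| ||y||) (the
    un-centered correlation), merged by complete linkage and cut into exactly
    ``k`` groups.  Groups are renumbered by increasing size with ties broken by
    first sample index, so "group 1" is the smallest, most deviant cluster —
    the convention used when singling out the aberrant tumor group.
    """
    tfa = np.asarray(tfa, dtype=float)
    n_samples = tfa.shape[1]
    if k > n_samples:
        raise ValueError("k exceeds the number of samples")
    if np.any(np.linalg.norm(tfa, axis=0) == 0):
        raise ValueError("all-zero sample vector: cosine distance undefined")
    dist = pdist(tfa.T, metric="cosine")
    Z = linkage(dist, method="complete")
    raw = fcluster(Z, t=k, criterion="maxclust")
    if len(np.unique(raw)) != k:
        raise ValueError(f"could not cut the dendrogram into exactly {k} groups")
    order = sorted(np.unique(raw),
                   key=lambda c: (np.sum(raw == c), int(np.argmax(raw == c))))
    relabel = {c: i + 1 for i, c in enumerate(order)}
    labels = np.array([relabel[c] for c in raw])
    return ClusterResult(linkage_matrix=Z, group_labels=labels, k=k,
                         leaf_order=tuple(int(i) for i in leaves_list(Z)))


@dataclass
class Association:
    table: np.ndarray  # 2x2: (group 1, pooled rest) x status levels
    chi2: float
    p: float
    log10_p: float


def associate_status(groups: np.ndarray, status: np.ndarray,
                     group1: int = 1) -> Association:
    """Pearson chi-squared association of group membership with binary status.

    The contingency table opposes ``group1`` to all remaining groups pooled
    (the group-1-vs-rest scheme used when three major clusters are observed).
    No continuity correction is applied; 1 degree of freedom.
    """
    groups = np.asarray(groups)
    status = np.asarray(status)
    if groups.shape != status.shape:
        raise ValueError("groups and status must align")
    levels = np.unique(status)
    if len(levels) != 2:
        raise ValueError("status must be binary with both levels present")
    if len(np.unique(groups)) < 2:
        raise ValueError("need at least two groups")
    in1 = groups == group1
    table = np.array([[np.sum(in1 & (status == s)) for s in levels],
                      [np.sum(~in1 & (status == s)) for s in levels]], dtype=float)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero marginal in the contingency table: test undefined")
    chi2, p, _, _ = chi2_contingency(table, correction=False)
    return Association(table=table, chi2=float(chi2), p=float(p),
                       log10_p=float(np.log10(p)) if p > 0 else -np.inf)


def status_rates_by_group(groups: np.ndarray, status: np.ndarray,
                          positive=1) -> dict[int, float]:
    """Percent of status-positive samples per group, one-decimal rounding."""
    groups = np.asarray(groups)
    status = np.asarray(status)
    out = {}
    for g in np.unique(groups):
        sel = groups == g
        out[int(g)] = round(100.0 * np.sum(status[sel] == positive) / np.sum(sel), 1)
    return out


@dataclass
class TTestResult:
    t: np.ndarray
    p: np.ndarray
    tf_ids: tuple[str, ...]
    undefined: np.ndarray  # zero variance in both groups
    marks: dict[float, np.ndarray] = field(default_factory=dict)


def tfa_ttest(tfa: np.ndarray, group_a: np.ndarray, group_b: np.ndarray,
              tf_ids: tuple[str, ...] | None = None,
              equal_var: bool = True) -> TTestResult:
    """Two-sample t-test per TF row between two sample index sets.

    Pooled-variance (Student) by default; ``equal_var=False`` gives Welch.
    Rows with zero variance in both groups are flagged as undefined rather
    than silently reported.
    """
    tfa = np.asarray(tfa, dtype=float)
    group_a = np.asarray(group_a)
    group_b = np.asarray(group_b)
    if group_a.size < 2 or group_b.size < 2:
        raise ValueError("need at least 2 samples per side")
    xa, xb = tfa[:, group_a], tfa[:, group_b]
    undefined = (np.var(xa, axis=1) == 0) & (np.var(xb, axis=1) == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = ttest_ind(xa, xb, axis=1, equal_var=equal_var)
    t = np.where(undefined, np.nan, t)
    p = np.where(undefined, np.nan, p)
    if tf_ids is None:
        tf_ids = tuple(f"TF{i + 1:03d}" for i in range(tfa.shape[0]))
    marks = {thr: (p < thr) & ~undefined for thr in MARK_THRESHOLDS}
    return TTestResult(t=t, p=p, tf_ids=tf_ids, undefined=undefined, marks=marks)


def derive_status_signature(tfa: np.ndarray, status: np.ndarray,
                            alpha: float = 1e-4,
                            tf_ids: tuple[str, ...] | None = None,
                            equal_var: bool = True) -> list[str]:
    """TFs whose activity separates the two status groups at p < alpha.

    The default threshold of 1e-4 is the cut used to derive status signatures
    from IHC-annotated cohorts.
    """
    status = np.asarray(status)
    levels = np.unique(status)
    if len(levels) != 2:
        raise ValueError("status must be binary")
    res = tfa_ttest(tfa, np.flatnonzero(status == levels[0]),
                    np.flatnonzero(status == levels[1]),
                    tf_ids=tf_ids, equal_var=equal_var)
    hits = [(res.p[i], t) for i, t in enumerate(res.tf_ids)
            if np.isfinite(res.p[i]) and res.p[i] < alpha]
    return [t for _, t in sorted(hits, key=lambda x: (x[0], x[1]))]


@dataclass
class CorrelationResult:
    matrix: np.ndarray  # |Pearson r|, symmetric, unit diagonal
    order: tuple[int, ...]
    tf_ids: tuple[str, ...]
    constant_tfs: tuple[str, ...]


def tfa_correlation(tfa: np.ndarray,
                    tf_ids: tuple[str, ...] | None = None) -> CorrelationResult:
    """Absolute pairwise Pearson correlation between TFA rows, with a
    hierarchically clustered row/column ordering.

    Constant rows have undefined correlations: they are flagged, their
    off-diagonal entries set to 0, and they sort to the end of the ordering.
    """
    tfa = np.asarray(tfa, dtype=float)
    n_tfs, n_samples = tfa.shape
    if n_samples < 3:
        raise ValueError("need at least 3 samples for correlations")
    if tf_ids is None:
        tf_ids = tuple(f"TF{i + 1:03d}" for i in range(n_tfs))
    constant = np.std(tfa, axis=1) == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.corrcoef(tfa)
    mat = np.abs(r)
    mat[constant, :] = 0.0
    mat[:, constant] = 0.0
    np.fill_diagonal(mat, 1.0)
    if constant.any():
        logger.warning("tfa_correlation: constant TFA row(s): %s",
                       [tf_ids[i] for i in np.flatnonzero(constant)])
    usable = np.flatnonzero(~constant)
    if usable.size >= 3:
        d = pdist(mat[np.ix_(usable, usable)], metric="euclidean")
        order_usable = [int(usable[i]) for i in leaves_list(linkage(d, method="average"))]
    else:
        order_usable = [int(i) for i in usable]
    order = tuple(order_usable + [int(i) for i in np.flatnonzero(constant)])
    return CorrelationResult(matrix=mat, order=order, tf_ids=tf_ids,
                             constant_tfs=tuple(tf_ids[i] for i in np.flatnonzero(constant)))


def normalize_to_reference(tfa: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Center each TF's activities on its mean over the reference samples
    (the heatmap convention: values relative to the average of normal samples)."""
    tfa = np.asarray(tfa, dtype=float)
    reference = np.asarray(reference)
    if reference.size == 0:
        raise ValueError("empty reference sample set")
    return tfa - tfa[:, reference].mean(axis=1, keepdims=True)


@dataclass
class SignatureReport:
    """Bundle of the downstream analytics for one cohort."""

    cluster: ClusterResult
    association: Association
    ttest: TTestResult
    correlation: CorrelationResult
    group_status_rates: dict[int, float]


def build_report(tfa: np.ndarray, status: np.ndarray, k: int = 3,
                 tf_ids: tuple[str, ...] | None = None,
                 group1: int = 1, equal_var: bool = True) -> SignatureReport:
    """Cluster a cohort on its TFA signature and test the status association.

    The t-tests compare status-negative samples in group 1 against
    status-positive samples in the last group (the two ends of the clustering);
    samples lacking annotation in those groups are excluded.
    """
    status = np.asarray(status)
    res = cluster_samples(tfa, k)
    assoc = associate_status(res.group_labels, status, group1=group1)
    levels = np.unique(status)
    neg1 = np.flatnonzero((res.group_labels == group1) & (status == levels[0]))
    posk = np.flatnonzero((res.group_labels == res.group_labels.max())
                          & (status == levels[1]))
    if neg1.size >= 2 and posk.size >= 2:
        tt = tfa_ttest(tfa, neg1, posk, tf_ids=tf_ids, equal_var=equal_var)
    else:  # fall back to a straight status split when the corners are too small
        tt = tfa_ttest(tfa, np.flatnonzero(status == levels[0]),
                       np.flatnonzero(status == levels[1]),
                       tf_ids=tf_ids, equal_var=equal_var)
    corr = tfa_correlation(tfa, tf_ids=tf_ids)
    return SignatureReport(cluster=res, association=assoc, ttest=tt,
                           correlation=corr,
                           group_status_rates=status_rates_by_group(
                               res.group_labels, status, positive=levels[1]))
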