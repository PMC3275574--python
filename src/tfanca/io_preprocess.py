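"""Connectivity and expression I/O, and transformation to log-ratio matrices.

The decomposition downstream consumes two objects: a :class:`ConnectivityPattern`
(the bipartite TF -> target-gene zero pattern, TRED-style, with per-edge evidence
labels) and an :class:`ExpressionRatios` matrix E of log2 expression ratios
(genes x conditions) computed against a reference condition.  This module reads
and writes both as plain TSV, averages probesets to gene level, collapses
biological replicates on the linear scale before taking ratios, and provides the
fold-change gene filter used for descriptive up/down counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: evidence labels understood in connectivity tables
KNOWN_EVIDENCE = frozenset({"experimental", "motif"})


class ConnectivityError(ValueError):
    """Malformed or inconsistent connectivity input."""


@dataclass(frozen=True)
class ConnectivityPattern:
    """Bipartite TF -> gene connectivity constraining the decomposition.

    Edges are (gene, TF) pairs; ``evidence`` carries the per-edge provenance
    label (``experimental`` or ``motif``).  TF and gene order is significant:
    it fixes the row/column order of every matrix derived from the pattern.
    """

    tf_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]
    edges: frozenset[tuple[str, str]]
    evidence: Mapping[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        tfs, genes = set(self.tf_ids), set(self.gene_ids)
        for gene, tf in self.edges:
            if tf not in tfs or gene not in genes:
                raise ConnectivityError(f"edge ({gene!r}, {tf!r}) references unknown ids")

    @property
    def n_tfs(self) -> int:
        return len(self.tf_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def mask(self) -> np.ndarray:
        """Boolean (genes x TFs) incidence matrix in pattern order."""
        gi = {g: i for i, g in enumerate(self.gene_ids)}
        ti = {t: j for j, t in enumerate(self.tf_ids)}
        m = np.zeros((self.n_genes, self.n_tfs), dtype=bool)
        for gene, tf in self.edges:
            m[gi[gene], ti[tf]] = True
        return m

    def targets_of(self, tf: str) -> tuple[str, ...]:
        return tuple(g for g, t in sorted(self.edges) if t == tf)

    def regulators_of(self, gene: str) -> tuple[str, ...]:
        return tuple(t for g, t in sorted(self.edges) if g == gene)

    def restrict_edges(self, keep: Iterable[tuple[str, str]]) -> "ConnectivityPattern":
        """New pattern containing only ``keep`` edges; ids without any surviving
        edge are dropped (order otherwise preserved)."""
        keep = frozenset(keep)
        if not keep <= self.edges:
            raise ConnectivityError("restrict_edges: unknown edges requested")
        tfs_kept = {t for _, t in keep}
        genes_kept = {g for g, _ in keep}
        return ConnectivityPattern(
            tf_ids=tuple(t for t in self.tf_ids if t in tfs_kept),
            gene_ids=tuple(g for g in self.gene_ids if g in genes_kept),
            edges=keep,
            evidence={e: v for e, v in self.evidence.items() if e in keep},
        )


@dataclass
class ExpressionRatios:
    """Log2 expression-ratio matrix E (genes x non-reference conditions)."""

    gene_ids: tuple[str, ...]
    condition_ids: tuple[str, ...]
    values: np.ndarray
    reference_label: str = "reference"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.condition_ids)):
            raise ValueError("values shape does not match gene/condition ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ExpressionRatios requires finite entries only")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_conditions(self) -> int:
        return len(self.condition_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.gene_ids, name="gene"),
                            columns=list(self.condition_ids))

    def reorder_genes(self, gene_ids: Sequence[str]) -> "ExpressionRatios":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [idx[g] for g in gene_ids]
        return ExpressionRatios(tuple(gene_ids), self.condition_ids,
                                self.values[rows], self.reference_label)


@dataclass(frozen=True)
class Design:
    """Replicate design: condition -> sample columns, plus the reference group."""

    groups: Mapping[str, tuple[str, ...]]
    reference: str

    def __post_init__(self) -> None:
        if self.reference not in self.groups:
            raise ValueError(f"reference group {self.reference!r} not among groups")
        for cond, samples in self.groups.items():
            if len(samples) == 0:
                raise ValueError(f"empty replicate group {cond!r}")


# ---------------------------------------------------------------------------
# connectivity I/O

def load_connectivity(path, evidence_filter: Iterable[str] = ("experimental", "motif"),
                      ) -> ConnectivityPattern:
    """Read a 3-column TSV (TF, gene, evidence) into a ConnectivityPattern.

    Only edges whose evidence label is in ``evidence_filter`` are retained;
    duplicate edges are collapsed (first occurrence wins).  TFs or genes that
    lose every edge to the filter are dropped with a logged warning.  Ids are
    stored in sorted order, so write/read round-trips are exact.
    """
    evidence_filter = frozenset(evidence_filter)
    if not evidence_filter <= KNOWN_EVIDENCE:
        raise ConnectivityError(
            f"unknown evidence labels in filter: {sorted(evidence_filter - KNOWN_EVIDENCE)}")
    table = pd.read_csv(path, sep="\t", dtype=str)
    required = {"TF", "gene", "evidence"}
    if not required <= set(table.columns):
        raise ConnectivityError(f"connectivity table must have columns {sorted(required)}")
    if table[["TF", "gene", "evidence"]].isna().any().any():
        raise ConnectivityError("malformed connectivity rows (missing fields)")
    bad = set(table["evidence"]) - KNOWN_EVIDENCE
    if bad:
        raise ConnectivityError(f"unknown evidence labels in file: {sorted(bad)}")

    edges: dict[tuple[str, str], str] = {}
    seen_tfs: set[str] = set()
    for row in table.itertuples(index=False):
        seen_tfs.add(row.TF)
        if row.evidence not in evidence_filter:
            continue
        edges.setdefault((row.gene, row.TF), row.evidence)
    kept_tfs = {t for _, t in edges}
    dropped_tfs = seen_tfs - kept_tfs
    if dropped_tfs:
        logger.warning("dropped %d TF(s) with no edge surviving the evidence filter: %s",
                       len(dropped_tfs), sorted(dropped_tfs))
    return ConnectivityPattern(tuple(sorted(kept_tfs)),
                               tuple(sorted({g for g, _ in edges})),
                               frozenset(edges), edges)


def write_connectivity(pattern: ConnectivityPattern, path) -> None:
    """Write the pattern back to the 3-column TSV format read by
    :func:`load_connectivity` (row order follows gene, then TF, order)."""
    gi = {g: i for i, g in enumerate(pattern.gene_ids)}
    ti = {t: i for i, t in enumerate(pattern.tf_ids)}
    rows = sorted(pattern.edges, key=lambda e: (ti[e[1]], gi[e[0]]))
    frame = pd.DataFrame(
        {"TF": [t for _, t in rows],
         "gene": [g for g, _ in rows],
         "evidence": [pattern.evidence.get((g, t), "experimental") for g, t in rows]})
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# expression I/O

def read_expression(path) -> pd.DataFrame:
    """Read an expression TSV (first column gene/probe id, one column per sample)."""
    frame = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if not np.all(np.isfinite(frame.to_numpy(dtype=float))):
        raise ValueError("non-finite values in expression table")
    return frame.astype(float)


def write_expression(frame: pd.DataFrame, path) -> None:
    # %.17g guarantees binary round-trip of float64 values
    frame.to_csv(path, sep="\t", float_format="%.17g")


def write_ratios(ratios: ExpressionRatios, path) -> None:
    write_expression(ratios.to_frame(), path)


def read_ratios(path, reference_label: str = "reference") -> ExpressionRatios:
    frame = read_expression(path)
    return ExpressionRatios(tuple(frame.index), tuple(frame.columns),
                            frame.to_numpy(), reference_label)


# ---------------------------------------------------------------------------
# preprocessing operations

def average_probesets(expr: pd.DataFrame,
                      probe_to_gene: Mapping[str, str] | pd.DataFrame) -> pd.DataFrame:
    """Collapse probe-level rows to gene level by the arithmetic mean.

    ``probe_to_gene`` maps each probe id to at most one gene; a probe listed
    under two genes is an error (silent double counting is not reproducible).
    Probes without a mapping are dropped.
    """
    if isinstance(probe_to_gene, pd.DataFrame):
        pairs = list(zip(probe_to_gene.iloc[:, 0], probe_to_gene.iloc[:, 1]))
        mapping: dict[str, str] = {}
        for probe, gene in pairs:
            if probe in mapping and mapping[probe] != gene:
                raise ValueError(f"probe {probe!r} mapped to multiple genes")
            mapping[probe] = gene
    else:
        mapping = dict(probe_to_gene)
    keep = expr.index.intersection(mapping.keys())
    dropped = len(expr.index) - len(keep)
    if dropped:
        logger.info("average_probesets: %d unmapped probe(s) dropped", dropped)
    sub = expr.loc[keep]
    genes = pd.Index([mapping[p] for p in sub.index], name="gene")
    out = sub.groupby(genes, sort=False).mean()
    return out


def to_log_ratios(expr: pd.DataFrame, design: Design) -> ExpressionRatios:
    """Linear-scale expression -> log2 ratio matrix against the reference group.

    Biological replicates are averaged first (on the linear scale, which damps
    extreme individual log-ratios), then E[g, c] = log2(mean_c / mean_ref).
    The reference condition does not appear as a column of E.
    """
    values = expr.to_numpy(dtype=float)
    if np.any(values <= 0):
        raise ValueError("linear-scale expression must be strictly positive")
    missing = [s for ss in design.groups.values() for s in ss if s not in expr.columns]
    if missing:
        raise ValueError(f"design references unknown sample columns: {missing}")
    means = {cond: expr[list(samples)].mean(axis=1)
             for cond, samples in design.groups.items()}
    ref = means[design.reference]
    conditions = tuple(c for c in design.groups if c != design.reference)
    E = np.column_stack([np.log2(means[c].to_numpy() / ref.to_numpy())
                         for c in conditions])
    return ExpressionRatios(tuple(expr.index), conditions, E,
                            reference_label=design.reference)


@dataclass(frozen=True)
class FoldChangeResult:
    """Genes passing a fold-change cut, split by direction of maximal change."""

    genes: tuple[str, ...]
    up_genes: tuple[str, ...]
    down_genes: tuple[str, ...]
    threshold_fold: float

    @property
    def up_pct(self) -> float:
        return up_down_percentages(len(self.up_genes), len(self.down_genes))[0]

    @property
    def down_pct(self) -> float:
        return up_down_percentages(len(self.up_genes), len(self.down_genes))[1]


def up_down_percentages(n_up: int, n_down: int) -> tuple[float, float]:
    """Percent up / down among the selected genes, one-decimal rounding."""
    total = n_up + n_down
    if total == 0:
        return (0.0, 0.0)
    return (round(100.0 * n_up / total, 1), round(100.0 * n_down / total, 1))


def fold_change_filter(ratios: ExpressionRatios, threshold_fold: float) -> FoldChangeResult:
    """Genes whose |log2 ratio| reaches log2(threshold_fold) in any condition.

    A gene counts as *up* if its largest-magnitude change is positive, *down*
    otherwise.
    """
    if threshold_fold <= 1:
        raise ValueError("threshold_fold must exceed 1")
    cut = np.log2(threshold_fold)
    E = ratios.values
    hits = np.abs(E).max(axis=1) >= cut
    up, down, genes = [], [], []
    for i in np.flatnonzero(hits):
        genes.append(ratios.gene_ids[i])
        j = int(np.argmax(np.abs(E[i])))
        (up if E[i, j] > 0 else down).append(ratios.gene_ids[i])
    return FoldChangeResult(tuple(genes), tuple(up), tuple(down), threshold_fold)
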