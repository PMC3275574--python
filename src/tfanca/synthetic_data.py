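"""Ground-truth generators for every downstream stage of the pipeline.

The generator emulates the data regime the analysis assumes: a sparse,
identifiable TF -> gene connectivity pattern (tens of TFs, hundreds of target
genes), log-ratio expression E = A_true . P_true + Gaussian noise, a subset of
*perturbed* TFs whose activities shift between two condition groups, optional
planted spurious edges (present in the pattern, true strength zero), a
genome-like background gene pool for null sampling, and per-sample group and
binary status labels.

Identifiability is guaranteed by construction rather than rejection sampling:
every TF receives at least one exclusive target, which satisfies the reduced
structural-rank criterion deterministically.

Activity model.  Baseline activities are N(0, activity_sd^2); perturbed TFs
additionally gain a signed shift ``effect_size`` in the second condition group,
so the between-group mean activity difference is exactly ``effect_size``.
``activity_sd`` defaults to 1 (rich activity variation, the regime in which
recovery of A and P is meaningful).  Significance-calibration experiments set
``activity_sd=0``: under log-ratio semantics an unperturbed TF has activity
ratio ~ 0, and the random-genome null hypothesis of the modified z-test is then
exactly true for unperturbed TFs.

The background pool is built as ``pool_factor`` independent clone blocks of the
same network geometry (their own hidden TFs, strengths, perturbation settings
and noise), because a real genome is itself full of regulated, responsive genes
— not white noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io_preprocess import ConnectivityPattern, ExpressionRatios
from .nca_engine import check_identifiability


@dataclass
class SyntheticTruth:
    """Planted ground truth for one generated dataset."""

    pattern: ConnectivityPattern
    A_true: np.ndarray
    P_true: np.ndarray
    noise_sd: float
    perturbed_tfs: frozenset[str]
    spurious_edges: frozenset[tuple[str, str]]
    group_labels: tuple[str, ...]
    status_labels: tuple[int, ...]
    seed: int

    @property
    def true_pattern(self) -> ConnectivityPattern:
        """Pattern with spurious edges removed."""
        return self.pattern.restrict_edges(self.pattern.edges - self.spurious_edges)


@dataclass
class SyntheticDataset:
    truth: SyntheticTruth
    expression: ExpressionRatios
    background_pool: np.ndarray
    pool_gene_ids: tuple[str, ...]


def generate_pattern(n_tfs: int, n_genes: int, targets_per_tf: int,
                     seed: int = 0) -> ConnectivityPattern:
    """Random sparse connectivity with guaranteed identifiability.

    Each TF regulates exactly ``targets_per_tf`` genes, one of which is
    exclusive to it; every gene has at least one regulator.  Sizing must allow
    full gene coverage (n_tfs * targets_per_tf >= n_genes) and enough distinct
    shared genes per TF.
    """
    if n_genes < 2 * n_tfs:
        raise ValueError(f"too few genes: need n_genes >= 2*n_tfs ({2 * n_tfs}), got {n_genes}")
    if targets_per_tf < 2:
        raise ValueError("targets_per_tf must be at least 2")
    if n_tfs * targets_per_tf < n_genes:
        raise ValueError(
            "infeasible sizing: n_tfs * targets_per_tf must cover all genes")
    if n_genes - n_tfs < targets_per_tf - 1:
        raise ValueError(
            "infeasible sizing: not enough shareable genes for targets_per_tf")
    rng = np.random.default_rng(seed)
    tf_ids = tuple(f"TF{j + 1:03d}" for j in range(n_tfs))
    gene_ids = tuple(f"G{i + 1:04d}" for i in range(n_genes))
    order = rng.permutation(n_genes)
    exclusive = {tf_ids[j]: gene_ids[order[j]] for j in range(n_tfs)}
    shared_genes = [gene_ids[i] for i in order[n_tfs:]]

    edges: set[tuple[str, str]] = {(g, t) for t, g in exclusive.items()}
    budget = {t: targets_per_tf - 1 for t in tf_ids}
    # cover every shared gene first, then spend leftover budget at random
    for g in shared_genes:
        open_tfs = [t for t in tf_ids if budget[t] > 0
                    and (g, t) not in edges]
        t = open_tfs[rng.integers(len(open_tfs))]
        edges.add((g, t))
        budget[t] -= 1
    for t in tf_ids:
        candidates = [g for g in shared_genes if (g, t) not in edges]
        if budget[t] > len(candidates):
            raise ValueError("infeasible sizing: cannot complete targets_per_tf")
        if budget[t]:
            picks = rng.choice(len(candidates), size=budget[t], replace=False)
            for i in picks:
                edges.add((candidates[i], t))
            budget[t] = 0
    pattern = ConnectivityPattern(
        tf_ids=tf_ids, gene_ids=gene_ids, edges=frozenset(edges),
        evidence={e: "experimental" for e in edges})
    report = check_identifiability(pattern)
    if not report.identifiable:  # pragma: no cover - construction guarantees this
        raise RuntimeError("generated pattern unexpectedly non-identifiable")
    return pattern


def _exclusive_targets(pattern: ConnectivityPattern) -> set[str]:
    degree: dict[str, int] = {}
    for g, _ in pattern.edges:
        degree[g] = degree.get(g, 0) + 1
    return {g for g, d in degree.items() if d == 1}


def _activities(rng: np.random.Generator, tf_ids, n_conditions: int,
                group_b: np.ndarray, perturbed: list[str],
                effect_size: float, activity_sd: float,
                effect_jitter: float) -> np.ndarray:
    """Baseline N(0, activity_sd^2) activities plus signed group-B shifts.

    Each perturbed TF's per-condition shift is jittered around the effect size
    and recentred, so the between-group mean shift is exactly ``effect_size``
    while distinct perturbed TFs carry linearly independent activity patterns
    (a rank-deficient activity matrix would make attribution of the shared
    shift pattern to individual TFs non-unique).
    """
    P = activity_sd * rng.standard_normal((len(tf_ids), n_conditions))
    n_b = int(group_b.sum())
    for t in perturbed:
        sign = 1.0 if rng.random() < 0.5 else -1.0
        shifts = np.full(n_b, effect_size)
        if n_b > 1 and effect_jitter > 0:
            z = rng.standard_normal(n_b)
            shifts = effect_size + effect_jitter * (z - z.mean())
        P[tf_ids.index(t), group_b] += sign * shifts
    return P


def generate_dataset(n_tfs: int = 20, n_genes: int = 120, targets_per_tf: int = 6,
                     n_conditions: int = 8, n_perturbed: int = 4,
                     effect_size: float = 2.0, noise_sd: float = 0.1,
                     activity_sd: float = 1.0, effect_jitter: float | None = None,
                     fraction_spurious: float = 0.0,
                     pool_factor: int = 10, group_fraction: float = 0.5,
                     pool_responder_fraction: float = 0.02,
                     pool_activity_sd: float = 0.4,
                     seed: int = 0) -> SyntheticDataset:
    """Full synthetic study: truth, expression ratios and a background pool.

    Conditions are split into group A (first part) and group B; perturbed TFs
    shift their mean activity by ``effect_size`` in group B.  Control strengths
    are uniform in +-[0.5, 1.5] (random sign) so no true edge is numerically
    negligible.  ``fraction_spurious`` adds that fraction of extra zero-strength
    edges to the pattern (never on exclusive targets, preserving
    identifiability).  The pool holds ``pool_factor`` x n_genes genes generated
    as independent clone blocks of the same geometry.

    The pool is a genome emulation, not a clone of the study network: its
    hidden TFs carry quiet baseline activity (``pool_activity_sd``, default
    0.4 — sized so only a few percent of background genes exceed a 2-fold
    change by chance) and a small fraction of pool TFs
    (``pool_responder_fraction``, default 0.02 — the order of the strong
    responder rate seen genome-wide in perturbation experiments) respond at
    the study's effect size.  Both defaults are genome-scale constants and do
    not inherit the study network's activity settings.
    """
    if effect_size < 0 or noise_sd < 0:
        raise ValueError("effect_size and noise_sd must be nonnegative")
    if activity_sd < 0 or not 0 <= fraction_spurious < 1:
        raise ValueError("invalid activity_sd or fraction_spurious")
    if not 0 < group_fraction <= 1:
        raise ValueError("group_fraction must lie in (0, 1]")
    if n_perturbed > n_tfs:
        raise ValueError("n_perturbed exceeds n_tfs")
    if effect_jitter is None:
        effect_jitter = 0.5 * effect_size
    if not 0 <= pool_responder_fraction <= 1:
        raise ValueError("pool_responder_fraction must lie in [0, 1]")
    if pool_activity_sd < 0:
        raise ValueError("pool_activity_sd must be nonnegative")
    root = np.random.SeedSequence(seed)
    net_seed, block_root = root.spawn(2)
    rng = np.random.default_rng(net_seed)

    pattern = generate_pattern(n_tfs, n_genes, targets_per_tf,
                               seed=int(rng.integers(2**31)))
    tf_ids = list(pattern.tf_ids)

    # spurious edges: in the pattern, zero true strength, never on exclusive targets
    exclusive = _exclusive_targets(pattern)
    n_spurious = int(round(fraction_spurious * pattern.n_edges))
    spurious: set[tuple[str, str]] = set()
    if n_spurious:
        candidates = [(g, t) for g in pattern.gene_ids for t in tf_ids
                      if g not in exclusive and (g, t) not in pattern.edges]
        picks = rng.choice(len(candidates), size=min(n_spurious, len(candidates)),
                           replace=False)
        spurious = {candidates[i] for i in picks}
    full_edges = pattern.edges | spurious
    full_pattern = ConnectivityPattern(
        pattern.tf_ids, pattern.gene_ids, frozenset(full_edges),
        evidence={e: "experimental" for e in full_edges})

    mask_true = pattern.mask()
    A = np.where(mask_true,
                 rng.uniform(0.5, 1.5, mask_true.shape)
                 * rng.choice([-1.0, 1.0], mask_true.shape),
                 0.0)

    n_b = n_conditions - int(round((1 - group_fraction) * n_conditions))
    group_b = np.arange(n_conditions) >= (n_conditions - n_b)
    perturbed = list(rng.choice(tf_ids, size=n_perturbed, replace=False)) \
        if n_perturbed else []
    P = _activities(rng, tf_ids, n_conditions, group_b, perturbed,
                    effect_size, activity_sd, effect_jitter)
    E = A @ P + noise_sd * rng.standard_normal((n_genes, n_conditions))

    condition_ids = tuple(f"S{c + 1:03d}" for c in range(n_conditions))
    expression = ExpressionRatios(pattern.gene_ids, condition_ids, E)
    truth = SyntheticTruth(
        pattern=full_pattern, A_true=A, P_true=P, noise_sd=noise_sd,
        perturbed_tfs=frozenset(perturbed), spurious_edges=frozenset(spurious),
        group_labels=tuple("B" if b else "A" for b in group_b),
        status_labels=tuple(int(b) for b in group_b), seed=seed)

    # background pool: genome-like blocks of quiet, independently regulated genes
    total_pool_pert = int(round(pool_responder_fraction * n_tfs * pool_factor))
    per_block = np.bincount(rng.integers(pool_factor, size=total_pool_pert),
                            minlength=pool_factor) if total_pool_pert else \
        np.zeros(pool_factor, dtype=int)
    per_block = np.minimum(per_block, n_tfs)
    blocks = []
    pool_ids: list[str] = []
    for b, ss in enumerate(block_root.spawn(pool_factor)):
        brng = np.random.default_rng(ss)
        bpat = generate_pattern(n_tfs, n_genes, targets_per_tf,
                                seed=int(brng.integers(2**31)))
        bmask = bpat.mask()
        bA = np.where(bmask,
                      brng.uniform(0.5, 1.5, bmask.shape)
                      * brng.choice([-1.0, 1.0], bmask.shape),
                      0.0)
        bpert = list(brng.choice(list(bpat.tf_ids), size=int(per_block[b]),
                                 replace=False)) if per_block[b] else []
        bP = _activities(brng, list(bpat.tf_ids), n_conditions, group_b, bpert,
                         effect_size, pool_activity_sd, effect_jitter)
        blocks.append(bA @ bP + noise_sd * brng.standard_normal((n_genes, n_conditions)))
        pool_ids.extend(f"BG{b:02d}_{g}" for g in bpat.gene_ids)
    pool = np.vstack(blocks)
    return SyntheticDataset(truth=truth, expression=expression,
                            background_pool=pool, pool_gene_ids=tuple(pool_ids))


# ---------------------------------------------------------------------------
# on-disk form (same TSV formats io_preprocess consumes)

def write_dataset(dataset: SyntheticDataset, outdir) -> dict[str, str]:
    """Write expression, connectivity, pool, annotations and a truth sidecar."""
    from .io_preprocess import write_connectivity, write_ratios

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {name: str(outdir / fname) for name, fname in [
        ("expression", "expression.tsv"), ("connectivity", "connectivity.tsv"),
        ("pool", "background_pool.tsv"), ("annotations", "annotations.tsv"),
        ("truth", "truth_activities.tsv")]}
    write_ratios(dataset.expression, paths["expression"])
    write_connectivity(dataset.truth.pattern, paths["connectivity"])
    pd.DataFrame(dataset.background_pool,
                 index=pd.Index(dataset.pool_gene_ids, name="gene"),
                 columns=list(dataset.expression.condition_ids)
                 ).to_csv(paths["pool"], sep="\t")
    pd.DataFrame({"sample": dataset.expression.condition_ids,
                  "group": dataset.truth.group_labels,
                  "status": dataset.truth.status_labels}
                 ).to_csv(paths["annotations"], sep="\t", index=False)
    truth = dataset.truth
    rows = [(t, c, truth.P_true[i, j])
            for i, t in enumerate(truth.pattern.tf_ids)
            for j, c in enumerate(dataset.expression.condition_ids)]
    pd.DataFrame(rows, columns=["TF", "condition", "activity"]
                 ).to_csv(paths["truth"], sep="\t", index=False)
    return paths
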