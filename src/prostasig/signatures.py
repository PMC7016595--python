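"""Cell type-specific metagene discovery from sorted-cell expression data.

Each cell compartment is contrasted against the pooled remaining compartments
(one-vs-rest Welch t), significance is assessed by label permutation, the
permutation p-values are FDR-adjusted (Benjamini-Hochberg), and the top genes
by t per compartment form the metagene panel.  Panels are made pairwise
disjoint by assigning each gene to the compartment where its t statistic is
largest, so a gene marks exactly one cell type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger(__name__)

#: floor applied to each group variance so zero-variance genes never divide by 0
VARIANCE_FLOOR = 1e-8


@dataclass
class DifferentialResult:
    gene_id: str
    cell_type: str
    t_value: float
    p_perm: float
    q_value: float


@dataclass
class MetagenePanel:
    """One disjoint gene set per cell type plus the derivation statistics."""

    panel: GeneSetCollection
    stats: pd.DataFrame  # columns: gene_id, cell_type, t, p, q
    params: dict = field(default_factory=dict)


def _welch_t_matrix(values: np.ndarray, in_group: np.ndarray) -> np.ndarray:
    """Vectorised Welch t per gene for one binary split.

    ``values`` is genes x samples; ``in_group`` a boolean sample mask.
    Positive t means the target group mean exceeds the rest.  Each group
    variance is floored at VARIANCE_FLOOR; a gene constant everywhere gets
    t = 0 (zero numerator dominates).
    """
    a = values[:, in_group]
    b = values[:, ~in_group]
    n1, n2 = a.shape[1], b.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError(f"need >=2 samples per group, got {n1} vs {n2}")
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1 = np.maximum(a.var(axis=1, ddof=1), VARIANCE_FLOOR)
    v2 = np.maximum(b.var(axis=1, ddof=1), VARIANCE_FLOOR)
    return (m1 - m2) / np.sqrt(v1 / n1 + v2 / n2)


def _group_mask(expr: ExpressionMatrix, design: pd.Series, cell_type: str) -> np.ndarray:
    design = design.reindex(expr.sample_ids)
    if cell_type not in set(design.dropna()):
        raise ValueError(f"cell type {cell_type!r} absent from design")
    return (design == cell_type).to_numpy()


def one_vs_rest_t(expr: ExpressionMatrix, design: pd.Series, cell_type: str) -> pd.Series:
    """Welch t per gene for one cell type versus the pooled rest."""
    mask = _group_mask(expr, design, cell_type)
    t = _welch_t_matrix(expr.values, mask)
    return pd.Series(t, index=expr.gene_ids, name=f"t_{cell_type}")


def permutation_p(
    expr: ExpressionMatrix,
    design: pd.Series,
    cell_type: str,
    n_perm: int,
    seed: int,
) -> pd.Series:
    """Two-sided permutation p-values for the one-vs-rest t statistics.

    Sample labels are permuted uniformly at random (with replacement across
    permutations — uniqueness is not forced); the same label permutation is
    applied to every gene.  p = (1 + #{|t*| >= |t_obs|}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    rng = np.random.default_rng(seed)
    mask = _group_mask(expr, design, cell_type)
    values = expr.values
    t_obs = np.abs(_welch_t_matrix(values, mask))
    n = len(mask)
    exceed = np.zeros(values.shape[0], dtype=np.int64)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        t_star = np.abs(_welch_t_matrix(values, mask[perm]))
        exceed += t_star >= t_obs
    p = (1.0 + exceed) / (n_perm + 1.0)
    return pd.Series(p, index=expr.gene_ids, name=f"p_{cell_type}")


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p must be a non-empty 1-D vector")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def differential_table(
    expr: ExpressionMatrix,
    design: pd.Series,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-gene, per-cell-type t, permutation p and BH q (long format).

    All cell types share one permutation stream drawn from ``seed``: a single
    sequence of label shuffles is generated and each cell type's observed
    grouping is evaluated against it.
    """
    cell_types = sorted(set(design.dropna()))
    if len(cell_types) < 2:
        raise ValueError("design must contain >=2 cell types")
    rng = np.random.default_rng(seed)
    values = expr.values
    n = len(expr.sample_ids)
    masks = {ct: _group_mask(expr, design, ct) for ct in cell_types}
    for ct, mask in masks.items():
        if mask.sum() < 2:
            raise ValueError(f"cell type {ct!r} has <2 replicates")
    t_obs = {ct: _welch_t_matrix(values, m) for ct, m in masks.items()}
    exceed = {ct: np.zeros(values.shape[0], dtype=np.int64) for ct in cell_types}
    for _ in range(n_perm):
        perm = rng.permutation(n)
        for ct in cell_types:
            t_star = np.abs(_welch_t_matrix(values, masks[ct][perm]))
            exceed[ct] += t_star >= np.abs(t_obs[ct])
    frames = []
    for ct in cell_types:
        p = (1.0 + exceed[ct]) / (n_perm + 1.0)
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": expr.gene_ids,
                    "cell_type": ct,
                    "t": t_obs[ct],
                    "p": p,
                    "q": bh_fdr(p),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def extract_metagenes(
    expr: ExpressionMatrix,
    design: pd.Series,
    n_genes: int = 138,
    fdr_threshold: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> MetagenePanel:
    """Derive one disjoint metagene per cell type.

    Per cell type, genes with q < ``fdr_threshold`` and positive t are ranked
    by t descending; each gene is first assigned to the cell type where its t
    is largest (disjointness), then the top ``n_genes`` per set are kept.
    Sets may come back smaller than ``n_genes`` (logged) or empty.
    """
    stats = differential_table(expr, design, n_perm=n_perm, seed=seed)
    cell_types = sorted(set(design.dropna()))
    # widest t per gene decides ownership
    t_wide = stats.pivot(index="gene_id", columns="cell_type", values="t")
    owner = t_wide.idxmax(axis=1)
    sets: dict[str, list[str]] = {}
    for ct in cell_types:
        sub = stats[stats.cell_type == ct].set_index("gene_id")
        eligible = sub[(sub.q < fdr_threshold) & (sub.t > 0)]
        eligible = eligible[owner.loc[eligible.index] == ct]
        ranked = eligible.sort_values(["t", "gene_id"], ascending=[False, True], kind="mergesort")
        chosen = ranked.index[:n_genes].tolist()
        if len(chosen) < n_genes:
            logger.info(
                "cell type %s: only %d gene(s) qualify (requested %d)",
                ct, len(chosen), n_genes,
            )
        if chosen:
            sets[ct] = chosen
    panel = GeneSetCollection(sets=sets, descriptions={ct: f"{ct} metagene" for ct in sets})
    return MetagenePanel(
        panel=panel,
        stats=stats,
        params={
            "n_genes_per_set": n_genes,
            "fdr_threshold": fdr_threshold,
            "n_permutations": n_perm,
            "seed": seed,
        },
    )
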