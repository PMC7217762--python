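"""Gene selection and normalising transforms applied before decomposition.

The decomposition is fitted on the genes with the greatest variance in a
designated reference cohort (500 by default). Cross-dataset analyses first
restrict all matrices to the genes measured on every platform, pick one
probe per gene at random where platforms are probe-level, and map each
gene's distribution onto a standard normal (for profile correlations) or
onto the reference cohort's per-gene quantiles (to mitigate series-specific
effects when classifying external samples).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.stats import norm, rankdata

from .matrix import ExpressionMatrix

__all__ = [
    "select_top_variance_genes",
    "intersect_genes",
    "select_random_probe_per_gene",
    "inverse_normal_transform",
    "reference_quantiles",
    "quantile_map_to_reference",
]


def select_top_variance_genes(X: ExpressionMatrix, n: int = 500,
                              reference: ExpressionMatrix | None = None) -> ExpressionMatrix:
    """Restrict ``X`` to the ``n`` genes of greatest sample variance in ``reference``.

    Variance is the unbiased (n-1 denominator) sample variance computed in
    the reference matrix (``X`` itself when not given). Returned genes are in
    descending reference variance order.
    """
    ref = X if reference is None else reference
    shared = [g for g in ref.gene_ids if g in set(X.gene_ids)]
    if n > len(shared):
        raise ValueError(f"requested {n} genes but only {len(shared)} shared with reference")
    ref_shared = ref.subset_genes(shared)
    var = ref_shared.values.var(axis=1, ddof=1)
    order = np.argsort(-var, kind="stable")[:n]
    return X.subset_genes([shared[i] for i in order])


def intersect_genes(matrices: list[ExpressionMatrix]) -> list[ExpressionMatrix]:
    """Restrict every matrix to the common gene set, rows in identical order.

    Order follows the first matrix's gene order.
    """
    if len(matrices) < 2:
        raise ValueError("need at least two matrices to intersect")
    common = set(matrices[0].gene_ids)
    for m in matrices[1:]:
        common &= set(m.gene_ids)
    if not common:
        raise ValueError("gene sets have empty intersection")
    ordered = [g for g in matrices[0].gene_ids if g in common]
    return [m.subset_genes(ordered) for m in matrices]


def select_random_probe_per_gene(X: ExpressionMatrix, seed: int = 0) -> ExpressionMatrix:
    """Keep one probe per gene, chosen uniformly at random (seed-controlled).

    Requires ``X.probe_to_gene``; output rows are labelled by gene, ordered by
    first appearance of the gene among the probes.
    """
    if X.probe_to_gene is None:
        raise ValueError("matrix has no probe->gene map")
    rng = np.random.default_rng(seed)
    by_gene: dict[str, list[int]] = {}
    for i, probe in enumerate(X.gene_ids):
        gene = X.probe_to_gene.get(probe, probe)
        by_gene.setdefault(gene, []).append(i)
    rows, genes = [], []
    for gene, idxs in by_gene.items():
        rows.append(idxs[int(rng.integers(len(idxs)))] if len(idxs) > 1 else idxs[0])
        genes.append(gene)
    return ExpressionMatrix(X.values[rows], genes, list(X.sample_ids))


def inverse_normal_transform(X: ExpressionMatrix) -> ExpressionMatrix:
    """Map each gene's values to a standard normal via rank: Phi^-1((rank-0.5)/n).

    Ties get average ranks; a constant gene therefore becomes all zeros
    (warned). Output is invariant to any strictly monotone per-gene transform
    of the input.
    """
    if X.n_samples < 2:
        raise ValueError("inverse normal transform needs at least two samples")
    vals = X.values
    n = X.n_samples
    ranks = np.apply_along_axis(rankdata, 1, vals)  # average ranks
    out = norm.ppf((ranks - 0.5) / n)
    const = np.ptp(vals, axis=1) == 0
    if const.any():
        warnings.warn(f"{int(const.sum())} constant gene row(s) mapped to zeros")
    return ExpressionMatrix(out, list(X.gene_ids), list(X.sample_ids),
                            probe_to_gene=X.probe_to_gene)


def reference_quantiles(X: ExpressionMatrix) -> dict[str, np.ndarray]:
    """Per-gene sorted value vectors, stored with a model for projection-time mapping."""
    return {g: np.sort(X.values[i]) for i, g in enumerate(X.gene_ids)}


def quantile_map_to_reference(X: ExpressionMatrix,
                              ref_quantiles: dict[str, np.ndarray]) -> ExpressionMatrix:
    """Map each gene's values onto the reference distribution by rank.

    Within each gene row of ``X`` values receive average ranks; rank r out of
    n is mapped to the reference quantile at plotting position (r - 0.5)/n by
    linear interpolation between reference order statistics. A single sample
    therefore maps to the per-gene reference median. When ``X`` is the
    reference cohort itself the mapping is the identity.
    """
    missing = [g for g in X.gene_ids if g not in ref_quantiles]
    if missing:
        raise KeyError(f"{len(missing)} gene(s) absent from reference quantiles, "
                       f"e.g. {missing[:3]}")
    n = X.n_samples
    out = np.empty_like(X.values)
    for i, g in enumerate(X.gene_ids):
        ref = np.asarray(ref_quantiles[g], float)
        m = ref.shape[0]
        pos_ref = (np.arange(1, m + 1) - 0.5) / m
        ranks = rankdata(X.values[i])
        pos = (ranks - 0.5) / n
        out[i] = np.interp(pos, pos_ref, ref)
    return ExpressionMatrix(out, list(X.gene_ids), list(X.sample_ids),
                            probe_to_gene=X.probe_to_gene)
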