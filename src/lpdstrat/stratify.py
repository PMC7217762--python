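"""Clinical stratification and signature characterisation.

Turns decompositions into the clinical read-out: hard signature assignment
(largest gamma), the DESNT proportion with its four prognostic bands,
representative-run selection from a restart ensemble, cross-dataset
signature profile correlations, genomic-feature over-representation tests,
per-sample pathway activation scores, and per-signature differential
expression.

DESNT is the poor-prognosis signature: a sample is "DESNT cancer" when
DESNT is its most abundant signature, and the *proportion* of DESNT is used
as a continuous prognostic variable. The four bands are
``< 0.001``, ``[0.001, 0.3)``, ``[0.3, 0.6)`` and ``>= 0.6``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ExpressionMatrix
from .lpd import Decomposition, LPDModel, RunEnsemble
from . import preprocess

__all__ = [
    "assign_signature", "band_desnt", "stratification_table",
    "select_representative_run", "label_signatures",
    "signature_profile_correlation", "overrepresentation_test",
    "pathway_activation_scores", "rank_sets_by_desnt_correlation",
    "differential_expression", "consensus_differential_expression",
]

BAND_EDGES = (0.001, 0.3, 0.6)


def assign_signature(d: Decomposition) -> np.ndarray:
    """Hard assignment: the signature with the largest gamma per sample (0-based).

    Ties are broken toward the lowest index, with a warning.
    """
    gamma = d.gamma
    assigned = gamma.argmax(axis=1)
    is_tie = (gamma == gamma.max(axis=1, keepdims=True)).sum(axis=1) > 1
    if is_tie.any():
        warnings.warn(f"{int(is_tie.sum())} sample(s) with tied gamma assigned "
                      "to the lowest signature index")
    return assigned


def band_desnt(proportion):
    """Four-group banding of the DESNT proportion.

    Band 1: p < 0.001; band 2: 0.001 <= p < 0.3; band 3: 0.3 <= p < 0.6;
    band 4: p >= 0.6 (lower bounds inclusive).
    """
    p = np.asarray(proportion, float)
    scalar = p.ndim == 0
    p = np.atleast_1d(p)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("proportion outside [0, 1]")
    band = 1 + np.searchsorted(BAND_EDGES, p, side="right")
    return int(band[0]) if scalar else band


def stratification_table(d: Decomposition, desnt_index: int,
                         signature_labels=None) -> pd.DataFrame:
    """Per-sample stratification: assignment, DESNT proportion and band."""
    assigned = assign_signature(d)
    prop = d.theta[:, desnt_index]
    labels = signature_labels or [f"sig{k + 1}" for k in range(d.K)]
    return pd.DataFrame({
        "sample_id": d.sample_ids,
        "assigned_signature": [labels[k] for k in assigned],
        "desnt_proportion": prop,
        "desnt_band": band_desnt(prop),
    })


def select_representative_run(ensemble: RunEnsemble, clinical: pd.DataFrame,
                              desnt_index) -> int:
    """Pick the ensemble run whose DESNT log-rank p is closest to the mode.

    For each run, samples assigned to DESNT are compared with the rest by
    log-rank test; the mode of the log10 p-values is estimated by Gaussian
    kernel density (Silverman bandwidth) and the run minimising
    ``|log10 p - mode|`` is returned (index into the ensemble; ties go to the
    smaller seed).

    ``desnt_index`` is the DESNT signature's 0-based index, either one int
    for all runs or a sequence with one entry per run.
    """
    from .survival import logrank_test
    if clinical is None or not {"time", "event"} <= set(clinical.columns):
        raise ValueError("ensemble run selection needs a clinical table with "
                         "'time' and 'event' columns")
    idx = np.broadcast_to(np.asarray(desnt_index, int), (len(ensemble),))
    clin = clinical.set_index("sample_id") if "sample_id" in clinical.columns else clinical
    log10p = np.empty(len(ensemble))
    for i, run in enumerate(ensemble.runs):
        assigned = assign_signature(run.decomposition)
        in_desnt = assigned == idx[i]
        sub = clin.loc[run.decomposition.sample_ids]
        if in_desnt.all() or not in_desnt.any():
            warnings.warn(f"run {i}: no DESNT/non-DESNT split; p set to 1")
            p = 1.0
        else:
            _, _, p = logrank_test(sub["time"].to_numpy(), sub["event"].to_numpy(),
                                   in_desnt.astype(int))
        log10p[i] = np.log10(max(p, 1e-300))
        run.logrank_p = float(p)
    if len(ensemble) == 1:
        return 0
    if np.ptp(log10p) < 1e-12:
        return 0   # all runs identical: smallest seed (ensemble is seed-sorted)
    kde = stats.gaussian_kde(log10p, bw_method="silverman")
    grid = np.linspace(log10p.min(), log10p.max(), 512)
    mode = grid[np.argmax(kde(grid))]
    dist = np.abs(log10p - mode)
    # ties resolved toward the smaller seed: ensemble runs are seed-sorted
    return int(np.argmin(dist))


def label_signatures(model: LPDModel, reference_profiles: pd.DataFrame) -> list[str]:
    """Name each model signature after its best-correlated reference profile.

    ``reference_profiles``: genes x labels matrix of signature mean profiles
    (e.g. carrying the "DESNT" identity from a published decomposition).
    Greedy one-to-one matching on descending Pearson correlation of the
    shared-gene mu columns; unmatched signatures become ``unlabelled_k``.
    Requires >= 50% gene overlap.
    """
    shared = [g for g in model.gene_ids if g in reference_profiles.index]
    if len(shared) < 0.5 * model.n_genes:
        raise ValueError(f"only {len(shared)}/{model.n_genes} genes overlap "
                         "the reference (need >= 50%)")
    gidx = {g: i for i, g in enumerate(model.gene_ids)}
    mu = model.mu[[gidx[g] for g in shared], :]
    ref = reference_profiles.loc[shared]
    ref_labels = list(ref.columns)
    corr = np.zeros((model.K, len(ref_labels)))
    for k in range(model.K):
        for j in range(len(ref_labels)):
            corr[k, j] = np.corrcoef(mu[:, k], ref.iloc[:, j].to_numpy())[0, 1]
    labels = [f"unlabelled_{k + 1}" for k in range(model.K)]
    order = np.dstack(np.unravel_index(np.argsort(-corr, axis=None), corr.shape))[0]
    used_k, used_j = set(), set()
    for k, j in order:
        if k in used_k or j in used_j or not np.isfinite(corr[k, j]):
            continue
        labels[k] = ref_labels[j]
        used_k.add(int(k))
        used_j.add(int(j))
    return labels


def signature_profile_correlation(Xa: ExpressionMatrix, da: Decomposition,
                                  Xb: ExpressionMatrix, db: Decomposition,
                                  seed: int = 0) -> pd.Series:
    """Per-signature Pearson correlation of mean expression profiles across datasets.

    Four steps: (i) one probe per gene at random (when a probe map is
    present); (ii) per-gene inverse-normal transform; (iii) mean profile over
    the samples hard-assigned to each signature in each dataset; (iv)
    Pearson r between the two mean profiles, per signature. Signatures with
    no assigned sample in either dataset get NaN (flagged, not an error).
    """
    if da.K != db.K:
        raise ValueError("decompositions have different K")
    mats = []
    for X in (Xa, Xb):
        if X.probe_to_gene is not None:
            X = preprocess.select_random_probe_per_gene(X, seed=seed)
        mats.append(X)
    mats = preprocess.intersect_genes(mats)
    mats = [preprocess.inverse_normal_transform(X) for X in mats]
    assign_a, assign_b = assign_signature(da), assign_signature(db)
    out = {}
    for k in range(da.K):
        in_a = assign_a == k
        in_b = assign_b == k
        if not in_a.any() or not in_b.any():
            warnings.warn(f"signature {k + 1} has no assigned samples in one dataset")
            out[k + 1] = np.nan
            continue
        prof_a = mats[0].values[:, in_a].mean(axis=1)
        prof_b = mats[1].values[:, in_b].mean(axis=1)
        out[k + 1] = float(stats.pearsonr(prof_a, prof_b)[0])
    return pd.Series(out, name="pearson_r").rename_axis("signature")


def overrepresentation_test(assignments, binary_feature, signature: int,
                            correction: bool = True) -> dict:
    """Chi-square independence test of a binary feature vs membership of one signature.

    Builds the 2x2 table (in-signature vs rest) x (feature 1 vs 0) and applies
    Pearson's chi-square with Yates continuity correction by default (the R
    ``chisq.test`` convention for 2x2 tables).
    """
    assignments = np.asarray(assignments, int)
    feature = np.asarray(binary_feature, int)
    if set(np.unique(feature)) - {0, 1}:
        raise ValueError("feature must be binary 0/1")
    in_k = assignments == signature
    if not in_k.any() or in_k.all():
        raise ValueError("need samples both in and out of the signature")
    table = np.array([
        [int((in_k & (feature == 1)).sum()), int((in_k & (feature == 0)).sum())],
        [int((~in_k & (feature == 1)).sum()), int((~in_k & (feature == 0)).sum())],
    ])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate 2x2 table (zero margin)")
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=correction)
    return {"table": table, "chi2": float(chi2), "dof": int(dof),
            "p_value": float(p), "yates_correction": correction}


def pathway_activation_scores(X: ExpressionMatrix, gene_sets: dict,
                              min_genes: int = 3) -> pd.DataFrame:
    """Per-sample activation score for each gene set (samples x sets).

    Genes are z-scored across samples; a set's score in a sample is the mean
    z of its member genes present in the matrix. Sets with fewer than
    ``min_genes`` overlapping genes are dropped with a warning.
    """
    if not gene_sets:
        raise ValueError("empty gene-set collection")
    vals = X.values
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (vals - mean) / sd, 0.0)
    gidx = {g: i for i, g in enumerate(X.gene_ids)}
    cols, names, dropped = [], [], 0
    for name, members in gene_sets.items():
        rows = [gidx[g] for g in members if g in gidx]
        if len(rows) < min_genes:
            dropped += 1
            continue
        cols.append(z[rows].mean(axis=0))
        names.append(name)
    if dropped:
        warnings.warn(f"dropped {dropped} gene set(s) with < {min_genes} genes in matrix")
    if not names:
        raise ValueError("no gene set passed the overlap threshold")
    return pd.DataFrame(np.column_stack(cols), index=X.sample_ids, columns=names)


def rank_sets_by_desnt_correlation(scores: pd.DataFrame, theta_desnt,
                                   top_n: int = 20) -> pd.DataFrame:
    """Top gene sets by absolute Pearson correlation with the DESNT proportion.

    Constant score columns (undefined r) are excluded with a warning; ties in
    |r| are broken by set name.
    """
    theta = np.asarray(theta_desnt, float)
    rows = []
    n_dropped = 0
    for name in scores.columns:
        s = scores[name].to_numpy()
        if np.std(s) == 0 or np.std(theta) == 0:
            n_dropped += 1
            continue
        r = float(stats.pearsonr(s, theta)[0])
        rows.append((name, r, abs(r)))
    if n_dropped:
        warnings.warn(f"excluded {n_dropped} constant score column(s)")
    table = pd.DataFrame(rows, columns=["set", "pearson_r", "abs_r"])
    table = table.sort_values(["abs_r", "set"], ascending=[False, True],
                              kind="stable").reset_index(drop=True)
    if len(table) < top_n:
        warnings.warn(f"only {len(table)} sets available (top_n={top_n})")
        return table
    return table.head(top_n)


def differential_expression(X: ExpressionMatrix, assignments, signature: int,
                            fdr: float = 0.05) -> pd.DataFrame:
    """Per-gene Welch t-test of in-signature samples vs the rest, BH-adjusted.

    Returns a table (gene, effect = mean difference, t, p, q, significant);
    significance is BH q < ``fdr``. Requires >= 3 samples per side.
    """
    from statsmodels.stats.multitest import multipletests
    assignments = np.asarray(assignments, int)
    in_k = assignments == signature
    if in_k.sum() < 3 or (~in_k).sum() < 3:
        raise ValueError("need at least 3 samples on each side")
    a = X.values[:, in_k]
    b = X.values[:, ~in_k]
    t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.nan_to_num(p, nan=1.0)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame({
        "gene": X.gene_ids,
        "effect": a.mean(axis=1) - b.mean(axis=1),
        "t": t,
        "p": p,
        "q": q,
        "significant": q < fdr,
    })


def consensus_differential_expression(X: ExpressionMatrix, ensemble: RunEnsemble,
                                      desnt_index, fdr: float = 0.05,
                                      min_run_fraction: float = 0.5) -> pd.DataFrame:
    """Genes significant in at least a fraction of the restart runs.

    Cross-restart consensus filter: a gene counts as differentially expressed
    for the signature if it reaches BH q < ``fdr`` in at least
    ``min_run_fraction`` of the ensemble's runs (default half).
    """
    idx = np.broadcast_to(np.asarray(desnt_index, int), (len(ensemble),))
    counts = pd.Series(0, index=X.gene_ids, dtype=int)
    n_used = 0
    for i, run in enumerate(ensemble.runs):
        assigned = assign_signature(run.decomposition)
        try:
            table = differential_expression(X, assigned, idx[i], fdr=fdr)
        except ValueError:
            continue
        n_used += 1
        counts[table.loc[table["significant"], "gene"].to_numpy()] += 1
    if n_used == 0:
        raise ValueError("no run had enough samples on both sides")
    frac = counts / n_used
    out = pd.DataFrame({"gene": counts.index, "run_fraction": frac.to_numpy()})
    out["consensus"] = out["run_fraction"] >= min_run_fraction
    return out
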