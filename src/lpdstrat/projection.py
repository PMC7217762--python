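"""One-added-sample (OAS) projection onto a fitted decomposition.

New samples are decomposed into an existing model's signatures without
re-estimating the model parameters (mu, sigma2, alpha): only the sample's
own variational quantities Q and gamma are iterated to convergence. This is
what makes single-patient classification practical — the cohort-level fit
runs once, and each new expression profile is projected in milliseconds.

Because the training cohort's per-sample (Q, gamma) are themselves a fixed
point of these updates, reprojecting the training samples reproduces the
full decomposition's proportions.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix
from .lpd import LPDModel, Decomposition, _log_normal_matrix
from .preprocess import quantile_map_to_reference
from scipy.special import digamma

__all__ = ["project_sample", "project_dataset"]

MAX_MISSING_FRACTION = 0.10


def project_sample(e, model: LPDModel, max_iter: int = 500, tol: float = 1e-6):
    """Decompose one expression vector into the model's signatures.

    Parameters
    ----------
    e : per-gene expression vector aligned to ``model.gene_ids`` (already
        normalised onto the model's reference distribution). Missing genes
        may be NaN: up to 10% are dropped from the sums (with a warning);
        more is an error.

    Returns
    -------
    (gamma, theta_hat, n_iterations, converged) — ``gamma`` satisfies
    ``sum_k gamma_k = sum_k alpha_k + G_used``.
    """
    e = np.asarray(e, float).ravel()
    if e.shape[0] != model.n_genes:
        raise ValueError(f"expected {model.n_genes} genes, got {e.shape[0]}")
    present = np.isfinite(e)
    n_missing = int((~present).sum())
    if n_missing > MAX_MISSING_FRACTION * model.n_genes:
        raise ValueError(f"{n_missing}/{model.n_genes} genes missing "
                         f"(> {MAX_MISSING_FRACTION:.0%} tolerated)")
    if n_missing:
        warnings.warn(f"{n_missing} missing gene(s) dropped from projection sums")
    E = e[present][:, None]                                 # (G_used, 1)
    mu = model.mu[present]
    sigma2 = model.sigma2[present]
    alpha = model.alpha
    K = model.K
    G_used = int(present.sum())
    logN = _log_normal_matrix(E, mu, sigma2)[:, :, 0]       # (K, G_used)
    gamma = alpha + G_used / K                              # flat init
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        S = logN + digamma(gamma)[:, None]
        S -= S.max(axis=0, keepdims=True)
        Q = np.exp(S)
        Q /= Q.sum(axis=0, keepdims=True)
        gamma_new = alpha + Q.sum(axis=1)
        if np.max(np.abs(gamma_new - gamma)) < tol:
            gamma = gamma_new
            converged = True
            break
        gamma = gamma_new
    theta = gamma / gamma.sum()
    return gamma, theta, it, converged


def project_dataset(X, model: LPDModel, apply_normalization: bool = True,
                    max_iter: int = 500, tol: float = 1e-6) -> Decomposition:
    """Project every sample of ``X`` independently (order-independent).

    When the model stores reference quantiles and ``apply_normalization`` is
    true, the cohort is first quantile-mapped per gene onto the training
    distribution. Samples that fail to project are dropped with a warning;
    the rest are returned.
    """
    if isinstance(X, pd.DataFrame):
        X = ExpressionMatrix.from_frame(X)
    have = set(X.gene_ids)
    shared = [g for g in model.gene_ids if g in have]
    sub = X.subset_genes(shared)
    if apply_normalization and model.reference_quantiles is not None:
        sub = quantile_map_to_reference(sub, model.reference_quantiles)
    # absent model genes become NaN and are dropped per sample (<=10% tolerated)
    values = np.full((model.n_genes, X.n_samples), np.nan)
    model_pos = {g: i for i, g in enumerate(model.gene_ids)}
    values[[model_pos[g] for g in shared], :] = sub.values
    gammas, thetas, keep = [], [], []
    failures = []
    for j, sid in enumerate(sub.sample_ids):
        try:
            g, t, _, _ = project_sample(values[:, j], model,
                                        max_iter=max_iter, tol=tol)
        except ValueError as exc:
            failures.append((sid, str(exc)))
            continue
        gammas.append(g)
        thetas.append(t)
        keep.append(sid)
    if failures:
        warnings.warn(f"{len(failures)} sample(s) failed to project: "
                      f"{[s for s, _ in failures][:5]}")
    if not keep:
        raise ValueError("no sample could be projected")
    return Decomposition(sample_ids=keep, gamma=np.array(gammas),
                         theta=np.array(thetas))
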