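"""Latent process decomposition: Dirichlet/Gaussian mixed membership by variational EM.

Model
-----
For sample ``a`` with expression values ``e_ga`` over genes ``g``:

.. math::

    \\theta_a \\sim \\mathrm{Dirichlet}(\\alpha), \\quad
    z_{ga} \\mid \\theta_a \\sim \\mathrm{Categorical}(\\theta_a), \\quad
    e_{ga} \\mid z_{ga}=k \\sim \\mathcal{N}(\\mu_{gk}, \\sigma^2_{gk}).

Each of the K latent *signatures* is a full per-gene Gaussian expression
pattern; a sample is a mixture of signatures rather than a member of a single
cluster, which is what lets the model absorb intra-sample tumour
heterogeneity.

Inference is mean-field variational EM with ``q(\\theta_a) = Dir(\\gamma_a)``
and ``q(z_{ga}) = Q_{\\cdot ga}``:

.. math::

    Q_{kga} \\propto \\mathcal{N}(e_{ga}; \\mu_{gk}, \\sigma^2_{gk})
                     \\exp \\psi(\\gamma_{ak}), \\qquad
    \\gamma_{ak} = \\alpha_k + \\sum_g Q_{kga},

with responsibility-weighted Gaussian M-steps and, in "estimated" prior
mode, a damped-Newton update of the Dirichlet concentration ``alpha``
("uniform" mode holds ``alpha = 1`` fixed, the maximum-likelihood variant).
Every update is coordinate ascent on the evidence lower bound, so the bound
is non-decreasing across iterations; this is asserted during fitting.

The normalised proportions ``theta_hat = gamma / sum(gamma)`` are the
per-sample signature weights used downstream (DESNT proportion, survival).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln, polygamma, logsumexp

from .matrix import ExpressionMatrix
from . import preprocess

__all__ = [
    "LPDModel", "Decomposition", "FitOptions", "RunEnsemble", "RunRecord",
    "LatentProcessDecomposition", "LPDResults",
    "fit_lpd", "fit_restarts", "holdout_loglik", "select_n_signatures",
    "save_model", "load_model", "match_signatures",
]

VARIANCE_FLOOR = 1e-6
_MODEL_FORMAT = "lpdstrat-model"
_MODEL_VERSION = 1


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class LPDModel:
    """Fitted signature parameters: per-gene Gaussians and Dirichlet prior."""

    K: int
    gene_ids: list[str]
    mu: np.ndarray                  # (G, K)
    sigma2: np.ndarray              # (G, K)
    alpha: np.ndarray               # (K,)
    prior_mode: str = "uniform"     # {"uniform", "estimated"}
    reference_quantiles: dict[str, np.ndarray] | None = None
    signature_labels: list[str] | None = None
    fit_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, float)
        self.sigma2 = np.asarray(self.sigma2, float)
        self.alpha = np.asarray(self.alpha, float)
        G = len(self.gene_ids)
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.mu.shape != (G, self.K) or self.sigma2.shape != (G, self.K):
            raise ValueError("mu/sigma2 shape inconsistent with gene_ids and K")
        if self.alpha.shape != (self.K,) or np.any(self.alpha <= 0):
            raise ValueError("alpha must be K positive reals")
        if np.any(self.sigma2 < VARIANCE_FLOOR - 1e-15):
            raise ValueError("sigma2 below the variance floor")
        if self.prior_mode not in ("uniform", "estimated"):
            raise ValueError("prior_mode must be 'uniform' or 'estimated'")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


@dataclass
class Decomposition:
    """Variational decomposition of a cohort under an :class:`LPDModel`."""

    sample_ids: list[str]
    gamma: np.ndarray               # (A, K)
    theta: np.ndarray               # (A, K), rows sum to 1
    Q: np.ndarray | None = None     # (K, G, A) responsibilities
    bound: float = float("nan")

    @property
    def K(self) -> int:
        return self.gamma.shape[1]

    def to_frame(self, signature_labels=None) -> pd.DataFrame:
        labels = signature_labels or [f"theta_{k + 1}" for k in range(self.K)]
        df = pd.DataFrame(self.theta, index=pd.Index(self.sample_ids, name="sample_id"),
                          columns=labels)
        df["assigned_signature"] = self.theta.argmax(axis=1) + 1
        return df

    def to_tsv(self, path, signature_labels=None) -> None:
        # fixed float format so identical decompositions are byte-identical
        self.to_frame(signature_labels).to_csv(path, sep="\t", float_format="%.10g")


@dataclass
class FitOptions:
    """Knobs of the variational EM (defaults are the package's frozen contract)."""

    max_iterations: int = 2000
    bound_tolerance: float = 1e-6   # relative change of the bound
    variance_floor: float = VARIANCE_FLOOR
    seed: int = 0
    n_restarts: int = 1
    init_strategy: str = "gamma_noise"   # or "sample"
    store_q: bool = True

    def __post_init__(self) -> None:
        if self.bound_tolerance <= 0:
            raise ValueError("bound_tolerance must be positive")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")


@dataclass
class RunRecord:
    seed: int
    model: LPDModel
    decomposition: Decomposition
    bound: float
    logrank_p: float | None = None


@dataclass
class RunEnsemble:
    """Restart ensemble of independent fits, sorted by derived seed."""

    runs: list[RunRecord]

    def __post_init__(self) -> None:
        if not self.runs:
            raise ValueError("empty ensemble")
        if not all(np.isfinite(r.bound) for r in self.runs):
            raise ValueError("non-finite bound in ensemble")
        self.runs = sorted(self.runs, key=lambda r: r.seed)

    def __len__(self) -> int:
        return len(self.runs)

    def __getitem__(self, i) -> RunRecord:
        return self.runs[i]

    @property
    def bounds(self) -> list[float]:
        return [r.bound for r in self.runs]

    def best(self) -> RunRecord:
        return max(self.runs, key=lambda r: r.bound)


# ---------------------------------------------------------------------------
# numerical building blocks
# ---------------------------------------------------------------------------

def _log_normal_matrix(E: np.ndarray, mu: np.ndarray, sigma2: np.ndarray) -> np.ndarray:
    """log N(e_ga; mu_gk, sigma2_gk) as a (K, G, A) array."""
    muT = mu.T[:, :, None]          # (K, G, 1)
    s2T = sigma2.T[:, :, None]
    return -0.5 * (np.log(2 * np.pi * s2T) + (E[None, :, :] - muT) ** 2 / s2T)


def e_step(X: ExpressionMatrix, model: LPDModel, gamma_init: np.ndarray,
           n_iter: int = 1):
    """One (or more) coordinate updates of (Q, gamma) with model parameters fixed.

    Q_kga ∝ N(e_ga; mu_gk, sigma2_gk) * exp(psi(gamma_ak)), normalised over k;
    gamma_ak = alpha_k + sum_g Q_kga. After an update the additive identity
    sum_k gamma_ak = sum_k alpha_k + G holds for every sample.
    """
    if list(X.gene_ids) != list(model.gene_ids):
        raise ValueError("genes of X are not aligned to the model")
    E = X.values
    if not np.all(np.isfinite(E)):
        raise ValueError("non-finite expression values")
    logN = _log_normal_matrix(E, model.mu, model.sigma2)
    gamma = np.asarray(gamma_init, float).copy()
    Q = None
    for _ in range(n_iter):
        Q, gamma = _qg_update(logN, gamma, model.alpha)
    return Q, gamma


def _qg_update(logN: np.ndarray, gamma: np.ndarray, alpha: np.ndarray):
    S = logN + digamma(gamma).T[:, None, :]      # (K, G, A)
    S -= S.max(axis=0, keepdims=True)
    Q = np.exp(S)
    Q /= Q.sum(axis=0, keepdims=True)
    gamma_new = alpha[None, :] + Q.sum(axis=1).T
    return Q, gamma_new


def _fused_iteration(logN: np.ndarray, gamma: np.ndarray, alpha: np.ndarray):
    """One (Q, gamma) coordinate update plus the bound at the current parameters.

    Returns (Q, gamma_new, bound) where bound = ELBO(mu, sigma2, alpha;
    Q_new, gamma_new). The entropy of q(z) is taken from the softmax
    intermediates (sum Q log Q = sum Q*S - sum log Z), avoiding a second pass
    of transcendental evaluations over the (K, G, A) array.
    """
    psi_old = digamma(gamma)                     # (A, K)
    S = logN + psi_old.T[:, None, :]
    smax = S.max(axis=0, keepdims=True)
    S -= smax
    Q = np.exp(S)
    Z = Q.sum(axis=0, keepdims=True)
    Q /= Z
    Nk = Q.sum(axis=1).T                         # (A, K)
    gamma_new = alpha[None, :] + Nk
    elog = digamma(gamma_new) - digamma(gamma_new.sum(axis=1, keepdims=True))
    A = gamma.shape[0]
    # E_q[log p(e, z | theta)] + E_q[log p(theta)] - entropies;
    # sum Q log Q expanded through log Q = logN + psi_old - smax - log Z
    q_logn = float((Q * logN).sum())
    ent_z = q_logn + float((Nk * psi_old).sum()) - float(smax.sum()) \
        - float(np.log(Z).sum())
    lik = q_logn + float((Nk * elog).sum())
    dir_prior = A * (gammaln(alpha.sum()) - gammaln(alpha).sum()) \
        + float(((alpha - 1)[None, :] * elog).sum())
    ent_theta = float((gammaln(gamma_new.sum(axis=1)) - gammaln(gamma_new).sum(axis=1)
                       + ((gamma_new - 1) * elog).sum(axis=1)).sum())
    bound = dir_prior + lik - ent_theta - ent_z
    if not np.isfinite(bound):
        raise FloatingPointError("variational bound is not finite")
    return Q, gamma_new, bound


def m_step(X: ExpressionMatrix, Q: np.ndarray,
           variance_floor: float = VARIANCE_FLOOR):
    """Responsibility-weighted Gaussian updates.

    mu_gk = sum_a Q_kga e_ga / sum_a Q_kga;
    sigma2_gk = sum_a Q_kga (e_ga - mu_gk)^2 / sum_a Q_kga, floored.
    Components with zero total weight for a gene are reset to the gene's
    global mean/variance (warned).
    """
    E = X.values
    W = Q.sum(axis=2)                            # (K, G)
    empty = W <= 0
    Wsafe = np.where(empty, 1.0, W)
    mu = ((Q * E[None, :, :]).sum(axis=2) / Wsafe).T          # (G, K)
    resid2 = (Q * (E[None, :, :] - mu.T[:, :, None]) ** 2).sum(axis=2) / Wsafe
    sigma2 = np.maximum(resid2.T, variance_floor)
    if empty.any():
        warnings.warn(f"{int(empty.sum())} empty (gene, signature) cells reset "
                      "to global gene moments")
        gmean = E.mean(axis=1)
        gvar = np.maximum(E.var(axis=1), variance_floor)
        ke, ge = np.nonzero(empty)
        mu[ge, ke] = gmean[ge]
        sigma2[ge, ke] = gvar[ge]
    return mu, sigma2


def _dirichlet_mle(elog_mean: np.ndarray, alpha0: np.ndarray,
                   max_iter: int = 100, tol: float = 1e-9) -> np.ndarray:
    """Maximise sum_k (alpha_k - 1) s_k + lgamma(a0) - sum lgamma(alpha_k)
    given s_k = mean_a E[log theta_ak], by damped Newton (Minka's inversion)."""
    s = np.asarray(elog_mean, float)
    alpha = np.asarray(alpha0, float).copy()

    def objective(a):
        return gammaln(a.sum()) - gammaln(a).sum() + ((a - 1) * s).sum()

    f = objective(alpha)
    for _ in range(max_iter):
        g = digamma(alpha.sum()) - digamma(alpha) + s
        q = polygamma(1, alpha)                  # -H diagonal
        c = polygamma(1, alpha.sum())
        b = (g / q).sum() / (1.0 / c + (1.0 / q).sum())
        step = (g - b) / q
        if np.max(np.abs(step)) < tol * (1.0 + np.max(alpha)):
            return alpha
        new = alpha + step
        slack = 1e-12 * (abs(f) + 1.0)
        n_halve = 0
        while (np.any(new <= 0) or objective(new) < f - slack) and n_halve < 50:
            step *= 0.5
            new = alpha + step
            n_halve += 1
        if n_halve >= 50:
            warnings.warn("alpha Newton update did not improve; keeping previous alpha")
            return alpha
        f_new = objective(new)
        if np.max(np.abs(step)) < tol * (1.0 + np.max(alpha)) \
                or abs(f_new - f) < 1e-12 * (abs(f) + 1):
            return new
        alpha, f = new, f_new
    return alpha


def update_alpha(gamma: np.ndarray, alpha_current: np.ndarray,
                 prior_mode: str = "estimated") -> np.ndarray:
    """M-step for the Dirichlet concentration.

    In "uniform" mode alpha is held fixed; in "estimated" mode alpha maximises
    the bound's Dirichlet term given E[log theta_ak] = psi(gamma_ak) -
    psi(sum_k gamma_ak).
    """
    if prior_mode == "uniform":
        return np.asarray(alpha_current, float)
    elog = digamma(gamma) - digamma(gamma.sum(axis=1, keepdims=True))
    return _dirichlet_mle(elog.mean(axis=0), alpha_current)


def variational_bound(X: ExpressionMatrix, model: LPDModel,
                      Q: np.ndarray, gamma: np.ndarray) -> float:
    """Evidence lower bound E_q[log p(e, z, theta)] - E_q[log q]."""
    E = X.values
    alpha = model.alpha
    logN = _log_normal_matrix(E, model.mu, model.sigma2)
    elog = digamma(gamma) - digamma(gamma.sum(axis=1, keepdims=True))  # (A, K)
    A = gamma.shape[0]
    Nk = Q.sum(axis=1).T                                               # (A, K)
    dir_prior = A * (gammaln(alpha.sum()) - gammaln(alpha).sum()) \
        + ((alpha - 1)[None, :] * elog).sum()
    lik = (Q * logN).sum() + (Nk * elog).sum()
    ent_theta = (gammaln(gamma.sum(axis=1)) - gammaln(gamma).sum(axis=1)
                 + ((gamma - 1) * elog).sum(axis=1)).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        ent_z = np.where(Q > 0, Q * np.log(Q), 0.0).sum()
    bound = dir_prior + lik - ent_theta - ent_z
    if not np.isfinite(bound):
        raise FloatingPointError("variational bound is not finite")
    return float(bound)


def match_signatures(mu_a: np.ndarray, mu_b: np.ndarray) -> np.ndarray:
    """Optimal one-to-one signature alignment (Hungarian on mu-column correlation).

    Returns ``perm`` such that column k of ``mu_a`` matches column ``perm[k]``
    of ``mu_b``.
    """
    from scipy.optimize import linear_sum_assignment
    Ka, Kb = mu_a.shape[1], mu_b.shape[1]
    corr = np.zeros((Ka, Kb))
    for i in range(Ka):
        for j in range(Kb):
            ca = mu_a[:, i] - mu_a[:, i].mean()
            cb = mu_b[:, j] - mu_b[:, j].mean()
            denom = np.sqrt((ca ** 2).sum() * (cb ** 2).sum())
            corr[i, j] = (ca * cb).sum() / denom if denom > 0 else 0.0
    _, cols = linear_sum_assignment(-corr)
    return cols


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class LatentProcessDecomposition:
    """Mixed-membership decomposition model of an expression cohort.

    Parameters
    ----------
    X : ExpressionMatrix or DataFrame (genes x samples)
    n_signatures : number of latent signatures K
    prior : "uniform" (alpha fixed at 1, maximum-likelihood variant) or
        "estimated" (alpha re-estimated each M-step by damped Newton)
    store_reference_quantiles : keep per-gene sorted training values inside
        the fitted model so external samples can be quantile-mapped onto the
        training distribution before projection.
    """

    def __init__(self, X, n_signatures: int, prior: str = "uniform",
                 variance_floor: float = VARIANCE_FLOOR,
                 store_reference_quantiles: bool = True):
        if isinstance(X, pd.DataFrame):
            X = ExpressionMatrix.from_frame(X)
        if n_signatures < 1:
            raise ValueError("n_signatures must be >= 1")
        if X.n_samples < n_signatures:
            raise ValueError("need at least K samples to fit K signatures")
        if prior not in ("uniform", "estimated"):
            raise ValueError("prior must be 'uniform' or 'estimated'")
        self.X = X
        self.K = int(n_signatures)
        self.prior = prior
        self.variance_floor = float(variance_floor)
        self.store_reference_quantiles = store_reference_quantiles

    # -- initialisation ------------------------------------------------------
    def _initial_state(self, options: FitOptions, rng: np.random.Generator):
        E, K = self.X.values, self.K
        G = E.shape[0]
        alpha = np.ones(K)
        gamma = alpha[None, :] + G / K \
            + rng.uniform(0, 0.1 * G / K, size=(self.X.n_samples, K))
        gmean = E.mean(axis=1)
        gvar = np.maximum(E.var(axis=1), self.variance_floor)
        if options.init_strategy == "sample":
            # seed each signature's mean profile with a random training sample
            picks = rng.choice(self.X.n_samples, size=K, replace=False)
            mu = E[:, picks].copy()
        elif options.init_strategy == "gamma_noise":
            # jitter of 0.1 gene-sd breaks the exchangeable-signature saddle;
            # without it EM can stall in a near-symmetric state
            mu = gmean[:, None] + 0.1 * np.sqrt(gvar)[:, None] \
                * rng.standard_normal((G, K))
        else:
            raise ValueError(f"unknown init_strategy {options.init_strategy!r}")
        sigma2 = np.tile(gvar[:, None], (1, K))
        return mu, sigma2, alpha, gamma

    # -- fitting ---------------------------------------------------------------
    def fit(self, options: FitOptions | None = None,
            warm_start: "LPDResults | None" = None, **kwargs) -> "LPDResults":
        """Run variational EM to convergence; returns :class:`LPDResults`.

        The bound is asserted non-decreasing (1e-8 relative slack) at every
        iteration; an empty-signature re-seed restarts that baseline.
        ``warm_start`` continues from a previous fit's state (e.g. refining a
        uniform-prior solution with alpha estimation switched on).
        """
        options = options or FitOptions(**kwargs)
        rng = np.random.default_rng(options.seed)
        X, K = self.X, self.K
        E = X.values
        G, A = E.shape
        if warm_start is not None:
            mu = warm_start.model.mu.copy()
            sigma2 = warm_start.model.sigma2.copy()
            alpha = warm_start.model.alpha.copy()
            gamma = warm_start.decomposition.gamma.copy()
        else:
            mu, sigma2, alpha, gamma = self._initial_state(options, rng)
        gmean = E.mean(axis=1)
        gvar = np.maximum(E.var(axis=1), self.variance_floor)

        prev_bound = -np.inf
        bound = np.nan
        converged = False
        n_reseeds = 0
        Q = None
        it = 0
        # estimated mode runs in two stages: alpha stays at 1 until the
        # Gaussian parameters converge, then alpha estimation switches on
        # (premature sparsification of alpha locks in poor optima). Both
        # stages ascend the same bound, so monotonicity is unbroken.
        estimating_alpha = self.prior == "estimated" and warm_start is not None
        for it in range(1, options.max_iterations + 1):
            logN = _log_normal_matrix(E, mu, sigma2)
            # bound evaluated at the *current* parameters with the fresh (Q, gamma)
            Q, gamma, bound = _fused_iteration(logN, gamma, alpha)
            if np.isfinite(prev_bound):
                slack = 1e-8 * (abs(prev_bound) + 1.0)
                if bound < prev_bound - slack:
                    raise FloatingPointError(
                        f"variational bound decreased at iteration {it}: "
                        f"{prev_bound:.6f} -> {bound:.6f}")
                if abs(bound - prev_bound) < options.bound_tolerance * (abs(prev_bound) + 1.0):
                    if self.prior == "estimated" and not estimating_alpha:
                        estimating_alpha = True
                    else:
                        converged = True
                        break
            prev_bound = bound
            mu, sigma2 = m_step(X, Q, self.variance_floor)
            if estimating_alpha:
                alpha = update_alpha(gamma, alpha, "estimated")
            # degenerate empty signature: re-seed from the worst-fit sample
            mass = gamma.sum(axis=0) - A * alpha
            weak = np.nonzero(mass < 1e-3 * G)[0]
            if weak.size:
                theta = gamma / gamma.sum(axis=1, keepdims=True)
                per_sample_ll = _predictive_loglik(E, mu, sigma2, theta)
                worst = int(np.argmin(per_sample_ll))
                for k in weak:
                    mu[:, k] = E[:, worst]
                    sigma2[:, k] = gvar
                warnings.warn(f"re-seeded {weak.size} empty signature(s) at iteration {it}")
                n_reseeds += weak.size
                prev_bound = -np.inf   # reseed restarts the monotonicity baseline
        if not converged:
            warnings.warn(f"EM did not converge in {options.max_iterations} iterations")

        theta = gamma / gamma.sum(axis=1, keepdims=True)
        ref_q = preprocess.reference_quantiles(X) if self.store_reference_quantiles else None
        model = LPDModel(
            K=K, gene_ids=list(X.gene_ids), mu=mu, sigma2=sigma2, alpha=alpha,
            prior_mode=self.prior, reference_quantiles=ref_q,
            fit_meta={"seed": options.seed, "iterations": it, "final_bound": bound,
                      "tolerance": options.bound_tolerance, "converged": converged,
                      "n_reseeds": n_reseeds, "init_strategy": options.init_strategy},
        )
        decomposition = Decomposition(
            sample_ids=list(X.sample_ids), gamma=gamma, theta=theta,
            Q=Q if options.store_q else None, bound=bound,
        )
        return LPDResults(model, decomposition, converged=converged, n_iter=it)

    def fit_restarts(self, n_restarts: int = 100, seed: int = 0,
                     options: FitOptions | None = None, **kwargs) -> RunEnsemble:
        """Independent fits from distinct derived seeds (default 100 restarts).

        Each run is fully determined by its own derived seed, so results are
        independent of execution order and reproducible from the master seed.
        """
        base = options or FitOptions(**kwargs)
        run_seeds = derive_seeds(seed, n_restarts)
        runs, failures = [], []
        for s in run_seeds:
            opts = FitOptions(max_iterations=base.max_iterations,
                              bound_tolerance=base.bound_tolerance,
                              variance_floor=base.variance_floor, seed=int(s),
                              init_strategy=base.init_strategy, store_q=base.store_q)
            try:
                res = self.fit(opts)
            except FloatingPointError as exc:   # pragma: no cover - defensive
                failures.append((int(s), str(exc)))
                continue
            runs.append(RunRecord(seed=int(s), model=res.model,
                                  decomposition=res.decomposition, bound=res.bound))
        if not runs:
            raise RuntimeError(f"all {n_restarts} restarts failed: {failures[:3]}")
        if failures:
            warnings.warn(f"{len(failures)} restart(s) failed and were dropped")
        return RunEnsemble(runs)


def derive_seeds(master_seed: int, n: int) -> np.ndarray:
    """n distinct deterministic child seeds (< 2^31) from a master seed."""
    state = np.random.SeedSequence(int(master_seed)).generate_state(n, dtype=np.uint64)
    return (state % np.uint64(2 ** 31 - 1)).astype(np.int64)


class LPDResults:
    """Results of a converged decomposition: parameters + per-sample proportions."""

    def __init__(self, model: LPDModel, decomposition: Decomposition,
                 converged: bool, n_iter: int):
        self.model = model
        self.decomposition = decomposition
        self.converged = converged
        self.n_iter = n_iter

    @property
    def bound(self) -> float:
        return self.decomposition.bound

    @property
    def theta(self) -> np.ndarray:
        return self.decomposition.theta

    @property
    def gamma(self) -> np.ndarray:
        return self.decomposition.gamma

    def project(self, X, **kwargs) -> Decomposition:
        """OAS projection of new samples onto the fitted signatures."""
        from .projection import project_dataset
        return project_dataset(X, self.model, **kwargs)

    def holdout_loglik(self, X_test) -> float:
        return holdout_loglik(X_test, self.model)

    def save(self, path) -> None:
        save_model(self.model, path)

    def summary(self) -> str:
        m, d = self.model, self.decomposition
        lines = [
            "Latent Process Decomposition Results",
            "=" * 52,
            f"Signatures (K):        {m.K}",
            f"Genes:                 {m.n_genes}",
            f"Samples:               {len(d.sample_ids)}",
            f"Prior mode:            {m.prior_mode}",
            f"Converged:             {self.converged} ({self.n_iter} iterations)",
            f"Final bound:           {d.bound:.4f}",
            f"alpha:                 " + " ".join(f"{a:.4f}" for a in m.alpha),
            "",
            "Mean signature proportions (theta_hat):",
        ]
        labels = m.signature_labels or [f"sig{k + 1}" for k in range(m.K)]
        for k, lab in enumerate(labels):
            lines.append(f"  {lab:<12} {d.theta[:, k].mean():.4f}")
        return "\n".join(lines)

    def plot_proportions(self, ax=None, sort_by: int | None = None):
        """Stacked-bar plot of per-sample signature proportions (Fig 2a style)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3))
        theta = self.theta
        order = np.argsort(-theta[:, sort_by]) if sort_by is not None \
            else np.arange(theta.shape[0])
        bottom = np.zeros(theta.shape[0])
        for k in range(self.model.K):
            ax.bar(np.arange(theta.shape[0]), theta[order, k], bottom=bottom,
                   width=1.0, label=f"sig{k + 1}")
            bottom += theta[order, k]
        ax.set_xlabel("sample")
        ax.set_ylabel("signature proportion")
        ax.set_ylim(0, 1)
        ax.legend(fontsize=7, ncol=2)
        return ax


# ---------------------------------------------------------------------------
# functional front-ends
# ---------------------------------------------------------------------------

def fit_lpd(X, K: int, options: FitOptions | None = None,
            prior: str = "uniform", **kwargs):
    """Fit a K-signature decomposition; returns ``(LPDModel, Decomposition)``."""
    res = LatentProcessDecomposition(X, K, prior=prior).fit(options, **kwargs)
    return res.model, res.decomposition


def fit_restarts(X, K: int, n_restarts: int = 100, seed: int = 0,
                 prior: str = "uniform", options: FitOptions | None = None,
                 **kwargs) -> RunEnsemble:
    return LatentProcessDecomposition(X, K, prior=prior).fit_restarts(
        n_restarts=n_restarts, seed=seed, options=options, **kwargs)


def _predictive_loglik(E: np.ndarray, mu: np.ndarray, sigma2: np.ndarray,
                       theta: np.ndarray) -> np.ndarray:
    """Per-sample sum_g log sum_k theta_ak N(e_ga; mu_gk, sigma2_gk)."""
    logN = _log_normal_matrix(E, mu, sigma2)               # (K, G, A)
    with np.errstate(divide="ignore"):
        w = np.log(theta.T)[:, None, :]                    # (K, 1, A)
    return logsumexp(logN + w, axis=0).sum(axis=0)         # (A,)


def holdout_loglik(X_test, model: LPDModel) -> float:
    """Mean per-sample predictive log-likelihood of held-out samples.

    Each sample's gamma is estimated by the projection E-step with model
    parameters fixed, then scored under the signature mixture at
    theta_hat = gamma / sum(gamma).
    """
    from .projection import project_dataset
    if isinstance(X_test, pd.DataFrame):
        X_test = ExpressionMatrix.from_frame(X_test)
    if X_test.n_samples == 0:
        raise ValueError("empty test set")
    d = project_dataset(X_test, model, apply_normalization=False)
    ll = _predictive_loglik(X_test.values, model.mu, model.sigma2, d.theta)
    return float(ll.mean())


@dataclass
class ModelSelection:
    """Cross-validated hold-out log-likelihood per K and prior mode."""

    table: pd.DataFrame      # index K, columns ["estimated", "uniform"]
    chosen_k: int


def select_n_signatures(X, k_range, n_folds: int = 5, seed: int = 0,
                        n_restarts: int = 1,
                        options: FitOptions | None = None) -> ModelSelection:
    """Choose K by sample-wise cross-validated hold-out log-likelihood.

    For each K and each prior mode ("estimated" and "uniform") the mean
    hold-out predictive log-likelihood over folds is computed; the chosen K
    maximises the estimated-alpha curve, ties broken by the uniform curve and
    then by smaller K.
    """
    if isinstance(X, pd.DataFrame):
        X = ExpressionMatrix.from_frame(X)
    k_range = sorted(set(int(k) for k in k_range))
    if not k_range:
        raise ValueError("empty K range")
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    A = X.n_samples
    rng = np.random.default_rng(seed)
    perm = rng.permutation(A)
    folds = np.array_split(perm, n_folds)
    if min(len(f) for f in folds) < 2:
        raise ValueError("a fold has fewer than 2 samples; reduce n_folds")
    base = options or FitOptions()

    rows = {}
    for K in k_range:
        scores = {"estimated": [], "uniform": []}
        for fold in folds:
            test_ids = [X.sample_ids[i] for i in fold]
            train_ids = [s for s in X.sample_ids if s not in set(test_ids)]
            X_train = X.subset_samples(train_ids)
            X_test = X.subset_samples(test_ids)
            run_seeds = derive_seeds(seed, n_restarts)
            best = {"estimated": None, "uniform": None}
            for s in run_seeds:
                opts = FitOptions(max_iterations=base.max_iterations,
                                  bound_tolerance=base.bound_tolerance,
                                  variance_floor=base.variance_floor, seed=int(s),
                                  init_strategy=base.init_strategy, store_q=False)
                uni = LatentProcessDecomposition(X_train, K, prior="uniform").fit(opts)
                # estimated-mode refinement continues from the uniform solution
                est = LatentProcessDecomposition(X_train, K, prior="estimated").fit(
                    opts, warm_start=uni)
                for mode, res in (("uniform", uni), ("estimated", est)):
                    if best[mode] is None or res.bound > best[mode].bound:
                        best[mode] = res
            for mode in ("estimated", "uniform"):
                # pool per-sample log-likelihoods across folds (weighted mean)
                scores[mode].append(
                    (holdout_loglik(X_test, best[mode].model), len(test_ids)))
        rows[K] = {
            mode: float(np.average([s for s, _ in v], weights=[w for _, w in v]))
            for mode, v in scores.items()
        }
    table = pd.DataFrame(rows).T[["estimated", "uniform"]]
    table.index.name = "K"
    # argmax under estimated mode; ties by uniform curve, then smaller K
    best = table.reset_index().sort_values(
        ["estimated", "uniform", "K"], ascending=[False, False, True], kind="stable")
    chosen = int(best["K"].iloc[0])
    return ModelSelection(table=table, chosen_k=chosen)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_model(model: LPDModel, path) -> None:
    """Serialise an :class:`LPDModel` to a documented JSON container."""
    payload = {
        "format": _MODEL_FORMAT,
        "version": _MODEL_VERSION,
        "K": model.K,
        "gene_ids": model.gene_ids,
        "mu": model.mu.tolist(),
        "sigma2": model.sigma2.tolist(),
        "alpha": model.alpha.tolist(),
        "prior_mode": model.prior_mode,
        "signature_labels": model.signature_labels,
        "reference_quantiles": (
            None if model.reference_quantiles is None
            else {g: v.tolist() for g, v in model.reference_quantiles.items()}),
        "fit_meta": model.fit_meta,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> LPDModel:
    """Load a model saved by :func:`save_model`; round-trips bit-exactly."""
    try:
        with open(path) as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: corrupted model file ({exc})") from exc
    if payload.get("format") != _MODEL_FORMAT:
        raise ValueError(f"{path}: not an lpdstrat model file")
    if payload.get("version") != _MODEL_VERSION:
        raise ValueError(f"{path}: unsupported model version {payload.get('version')}")
    ref = payload.get("reference_quantiles")
    return LPDModel(
        K=payload["K"],
        gene_ids=list(payload["gene_ids"]),
        mu=np.array(payload["mu"], float),
        sigma2=np.array(payload["sigma2"], float),
        alpha=np.array(payload["alpha"], float),
        prior_mode=payload["prior_mode"],
        signature_labels=payload.get("signature_labels"),
        reference_quantiles=(None if ref is None
                             else {g: np.array(v, float) for g, v in ref.items()}),
        fit_meta=payload.get("fit_meta", {}),
    )
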