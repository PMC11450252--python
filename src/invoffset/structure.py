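"""Model-based ancestry estimation and genotype PCA.

Ancestry follows the classic unsupervised admixture model: individual i's
dosage at locus l is Binomial(2, pi_il) with pi_il = sum_k Q_ik F_kl, where
Q holds per-individual ancestry proportions over K clusters and F the
cluster allele frequencies.  The likelihood is maximized by EM block
coordinate ascent (the frappe updates), which is monotone in the
log-likelihood; missing dosages are excluded from the likelihood rather
than imputed.

The number of clusters is assessed by masked-entry cross-validation:
genotype entries are hidden, the model refit, and squared prediction error
between hidden dosages and 2*pi accumulated — the analogue of the
hold-out procedure used by the ADMIXTURE program.  The error curve is
exposed rather than auto-thresholded; real data often lack a clear minimum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .genio import GenotypeMatrix

logger = logging.getLogger(__name__)

_EPS = 1e-9


@dataclass
class AncestryMatrix:
    """EM admixture fit: Q (n x K), F (K x L), log-likelihood trace."""

    Q: np.ndarray
    F: np.ndarray
    loglik: float
    K: int
    seed: int
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    converged: bool = True

    def __post_init__(self) -> None:
        if not np.allclose(self.Q.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("Q rows must sum to 1")
        if (self.Q < -1e-12).any() or (self.Q > 1 + 1e-12).any():
            raise ValueError("Q entries outside [0,1]")
        if (self.F < -1e-12).any() or (self.F > 1 + 1e-12).any():
            raise ValueError("F entries outside [0,1]")


def _loglik(d: np.ndarray, miss: np.ndarray, Q: np.ndarray,
            F: np.ndarray) -> float:
    pi = np.clip(Q @ F, _EPS, 1 - _EPS)
    ll = d * np.log(pi) + (2.0 - d) * np.log(1.0 - pi)
    return float(np.sum(ll[~miss]))


def estimate_ancestry(g: GenotypeMatrix | np.ndarray, K: int, seed: int = 0,
                      max_iter: int = 500, tol: float = 1e-4) -> AncestryMatrix:
    """Fit the K-cluster admixture model by EM block coordinate ascent."""
    if K < 1:
        raise ValueError("K must be >= 1")
    d = g.dosages if isinstance(g, GenotypeMatrix) else np.asarray(g, float)
    miss = np.isnan(d)
    d = np.where(miss, 0.0, d)           # masked out of every sum below
    w = np.where(miss, 0.0, 1.0)
    n, L = d.shape
    n_obs = w.sum(axis=1)                # non-missing loci per individual

    if K == 1:
        F = (w * d).sum(axis=0) / np.maximum(2.0 * w.sum(axis=0), _EPS)
        Q = np.ones((n, 1))
        ll = _loglik(d, miss, Q, np.clip(F, _EPS, 1 - _EPS)[None, :])
        return AncestryMatrix(Q=Q, F=F[None, :], loglik=ll, K=1, seed=seed,
                              loglik_trace=np.array([ll]))

    rng = np.random.default_rng(seed)
    Q = rng.dirichlet(np.ones(K), size=n)
    F = np.clip(rng.uniform(0.1, 0.9, size=(K, L)), _EPS, 1 - _EPS)

    trace = []
    prev = -np.inf
    converged = False
    for it in range(max_iter):
        pi = np.clip(Q @ F, _EPS, 1 - _EPS)
        # responsibilities summed over loci (standard EM updates)
        A = w * d / pi                   # n x L
        B = w * (2.0 - d) / (1.0 - pi)
        # Q update: Q_ik <- Q_ik/(2 Li) * sum_l [A*F + B*(1-F)]
        Qn = Q * (A @ F.T + B @ (1.0 - F).T)
        Q = Qn / np.maximum(2.0 * n_obs[:, None], _EPS)
        Q = np.clip(Q, _EPS, None)
        Q /= Q.sum(axis=1, keepdims=True)
        # F update
        num = F * (Q.T @ A)
        den = num + (1.0 - F) * (Q.T @ B)
        F = np.clip(num / np.maximum(den, _EPS), _EPS, 1 - _EPS)

        ll = _loglik(d, miss, Q, F)
        trace.append(ll)
        if ll - prev < tol and it > 0:
            converged = True
            break
        prev = ll

    if not converged:
        logger.warning("EM did not converge in %d iterations (K=%d)",
                       max_iter, K)
    return AncestryMatrix(Q=Q, F=F, loglik=trace[-1], K=K, seed=seed,
                          loglik_trace=np.array(trace), converged=converged)


@dataclass
class CrossValResult:
    """Masked-entry prediction error per K."""

    errors: dict[int, float]
    chosen_K: int
    mask_fraction: float
    n_folds: int
    seed: int


def cross_validate_K(g: GenotypeMatrix | np.ndarray, K_list,
                     mask_fraction: float = 0.1, n_folds: int = 3,
                     seed: int = 0, max_iter: int = 300,
                     tol: float = 1e-3) -> CrossValResult:
    """Hold-out cross-validation of the cluster count.

    Per fold a random mask of observed genotype entries is hidden, the
    model is refit on the rest, and mean squared error between the hidden
    dosages and their predictions 2*pi is accumulated per K.
    """
    if not 0.0 < mask_fraction <= 0.5:
        raise ValueError("mask_fraction must be in (0, 0.5]")
    d0 = g.dosages if isinstance(g, GenotypeMatrix) else np.asarray(g, float)
    rng = np.random.default_rng(seed)
    obs = np.argwhere(~np.isnan(d0))
    errors = {int(K): 0.0 for K in K_list}
    counts = {int(K): 0 for K in K_list}
    for fold in range(n_folds):
        sel = rng.random(len(obs)) < mask_fraction
        hidden = obs[sel]
        d = d0.copy()
        d[hidden[:, 0], hidden[:, 1]] = np.nan
        if np.all(np.isnan(d), axis=0).any():
            skip = np.flatnonzero(np.all(np.isnan(d), axis=0))
            logger.info("fold %d: %d loci fully masked, skipped", fold,
                        len(skip))
        for K in K_list:
            fit = estimate_ancestry(d, int(K), seed=seed + 1000 * fold + K,
                                    max_iter=max_iter, tol=tol)
            pred = 2.0 * np.clip(fit.Q @ fit.F, 0.0, 1.0)
            err = (d0[hidden[:, 0], hidden[:, 1]]
                   - pred[hidden[:, 0], hidden[:, 1]]) ** 2
            errors[int(K)] += float(np.sum(err))
            counts[int(K)] += len(err)
    errors = {K: errors[K] / max(counts[K], 1) for K in errors}
    chosen = min(errors, key=errors.get)
    return CrossValResult(errors=errors, chosen_K=chosen,
                          mask_fraction=mask_fraction, n_folds=n_folds,
                          seed=seed)


def pca_genotypes(g: GenotypeMatrix | np.ndarray,
                  n_axes: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Genotype PCA: mean-imputed, column-centred dosages through SVD.

    Returns (scores, explained_variance_fraction); all-missing loci are
    dropped.
    """
    d = g.dosages if isinstance(g, GenotypeMatrix) else np.asarray(g, float)
    if d.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    all_missing = np.all(np.isnan(d), axis=0)
    if all_missing.any():
        logger.info("dropping %d all-missing loci from PCA",
                    int(all_missing.sum()))
        d = d[:, ~all_missing]
    mu = np.nanmean(d, axis=0)
    x = np.where(np.isnan(d), mu, d) - mu
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    n_axes = min(n_axes, len(s))
    var = s ** 2
    frac = var / var.sum() if var.sum() > 0 else var
    return u[:, :n_axes] * s[:n_axes], frac[:n_axes]


def align_clusters(F_est: np.ndarray, F_true: np.ndarray) -> np.ndarray:
    """Greedy permutation of estimated clusters onto reference clusters
    (label-switching resolution for tests and reports)."""
    K = F_est.shape[0]
    remaining = list(range(K))
    perm = np.empty(K, dtype=int)
    for k in range(K):
        dists = [np.mean((F_est[j] - F_true[k]) ** 2) for j in remaining]
        pick = remaining[int(np.argmin(dists))]
        perm[k] = pick
        remaining.remove(pick)
    return perm


def write_q_matrix(a: AncestryMatrix, path) -> None:
    np.savetxt(path, a.Q, fmt="%.6f", delimiter=" ")


def write_p_matrix(a: AncestryMatrix, path) -> None:
    np.savetxt(path, a.F.T, fmt="%.6f", delimiter=" ")
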