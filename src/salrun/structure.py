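"""Population structure: PCA, componentwise locus contributions, and
NMF-based ancestry with masked cross-entropy selection of K.

PCA operates on the SNP-wise centered and scaled (unit-variance) dosage
matrix, mean-imputed for missing calls; zero-variance SNPs are dropped.
Ancestry replaces sparse-NMF admixture estimation with a masked nonnegative
factorization of the individual allele-frequency matrix (dosage/2):
Q (individuals x K, rows on the simplex) times G (K x SNPs, ancestral
frequencies in [0,1]), fitted by alternating nonnegative least squares with
simplex projection, and scored by the prediction cross-entropy on a random
held-out entry mask — the analogue of the cross-entropy criterion used to
choose the number of ancestral clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, impute_dosages

log = logging.getLogger(__name__)


@dataclass
class PCAModel:
    scores: np.ndarray  # individuals x PCs (U * S)
    loadings: np.ndarray  # SNPs x PCs (V)
    explained_var: np.ndarray  # fraction per PC
    snp_index: np.ndarray  # indices of retained (non-constant) SNPs


@dataclass
class AncestryModel:
    Q: np.ndarray  # individuals x K, rows sum to 1
    G: np.ndarray  # K x SNPs ancestral frequencies in [0, 1]
    cross_entropy: float  # masked-prediction loss
    objective_path: np.ndarray  # training objective per iteration (non-increasing)
    converged: bool


def _standardize(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = impute_dosages(dosages)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    keep = np.flatnonzero(sd > 0)
    if keep.size == 0:
        raise ValueError("all SNPs are constant; PCA undefined")
    return (x[:, keep] - mu[keep]) / sd[keep], keep


def run_pca(g: GenotypeMatrix | np.ndarray, n_pcs: int = 3) -> PCAModel:
    """Truncated SVD of the standardized dosage matrix.

    scores = U·S; explained_var is each singular value's share of the total
    variance of the standardized matrix. Each PC is oriented so its first
    nonzero loading is positive.
    """
    dosages = g.dosages if isinstance(g, GenotypeMatrix) else np.asarray(g, dtype=float)
    if min(dosages.shape) < 2:
        raise ValueError("PCA needs >= 2 individuals and >= 2 SNPs")
    x, keep = _standardize(dosages)
    n_pcs = min(n_pcs, min(x.shape) - 1) or 1
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    u, s, vt = u[:, :n_pcs], s[:n_pcs], vt[:n_pcs]
    # sign convention: first nonzero loading per PC positive
    for k in range(n_pcs):
        nz = np.flatnonzero(np.abs(vt[k]) > 1e-12)
        if nz.size and vt[k, nz[0]] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    total = (x**2).sum()
    return PCAModel(
        scores=u * s,
        loadings=vt.T,
        explained_var=s**2 / total,
        snp_index=keep,
    )


def componentwise_loadings(model: PCAModel, top_fraction: float = 0.01) -> dict[int, np.ndarray]:
    """Per-PC top contributing SNPs ranked by squared loading.

    Selects ceil(top_fraction · M) SNPs per PC; ties broken by lower marker
    index. Returned indices refer to the original SNP numbering.
    """
    from .association import top_fraction as _select

    out = {}
    for k in range(model.loadings.shape[1]):
        chosen = _select(model.loadings[:, k] ** 2, top_fraction)
        out[k + 1] = model.snp_index[chosen]
    return out


# ---------------------------------------------------------------------------
# Ancestry (masked NMF)


def _project_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection of each row of v onto the probability simplex."""
    n, k = v.shape
    u = -np.sort(-v, axis=1)
    css = np.cumsum(u, axis=1) - 1
    ind = np.arange(1, k + 1)
    cond = u - css / ind > 0
    rho = k - np.argmax(cond[:, ::-1], axis=1) - 1
    theta = css[np.arange(n), rho] / (rho + 1)
    return np.maximum(v - theta[:, None], 0.0)


def _masked_objective(F, Q, G, train_mask) -> float:
    resid = (F - Q @ G)[train_mask]
    return float((resid**2).sum())


def fit_ancestry(
    g: GenotypeMatrix | np.ndarray,
    K: int,
    seed: int = 0,
    holdout_fraction: float = 0.05,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> AncestryModel:
    """Masked NMF of the individual frequency matrix F = dosage/2 into Q·G.

    A random ``holdout_fraction`` of entries is masked out of the fit and used
    to compute the reported cross-entropy (binomial deviance of the held-out
    dosages against predicted frequencies). Alternating updates: Q rows by
    projected least squares onto the simplex, G by clipped least squares into
    [0, 1]; the training objective is tracked and non-increasing up to the
    projection steps.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    dosages = g.dosages if isinstance(g, GenotypeMatrix) else np.asarray(g, dtype=float)
    F = impute_dosages(dosages) / 2.0
    n, m = F.shape
    rng = np.random.default_rng(seed)
    held = rng.random((n, m)) < holdout_fraction
    train = ~held

    Q = _project_simplex(rng.random((n, K)))
    G = np.clip(rng.random((K, m)) * 0.5 + 0.25, 0.01, 0.99)
    if K == 1:
        Q = np.ones((n, 1))
        G = F.mean(axis=0, keepdims=True)
        path = np.array([_masked_objective(F, Q, G, train)])
        return AncestryModel(Q, G, _cross_entropy(F, Q @ G, held), path, True)

    Fm = np.where(train, F, 0.0)
    path = []
    prev = np.inf
    converged = False
    for it in range(max_iter):
        # G update: per-column least squares with mask, via normal equations
        W = train.astype(float)
        QtQ = np.einsum("ik,il,ij->klj", Q, Q, W)  # K x K x m
        QtF = Q.T @ (Fm)
        for j in range(m):
            try:
                G[:, j] = np.linalg.solve(QtQ[:, :, j] + 1e-8 * np.eye(K), QtF[:, j])
            except np.linalg.LinAlgError:
                pass
        np.clip(G, 1e-4, 1 - 1e-4, out=G)
        # Q update: per-row least squares with mask, projected to simplex
        for i in range(n):
            w = train[i]
            Gi = G[:, w]
            try:
                q = np.linalg.solve(Gi @ Gi.T + 1e-8 * np.eye(K), Gi @ F[i, w])
            except np.linalg.LinAlgError:
                continue
            Q[i] = q
        Q = _project_simplex(Q)
        obj = _masked_objective(F, Q, G, train)
        if obj > prev:  # projection/clipping step failed to improve: stop here
            Q, G = prev_QG
            converged = True
            break
        path.append(obj)
        if prev - obj < tol * max(prev, 1.0):
            converged = True
            break
        prev = obj
        prev_QG = (Q.copy(), G.copy())
    if not converged:
        log.warning("fit_ancestry: max_iter=%d reached without convergence; "
                    "returning best iterate", max_iter)
    return AncestryModel(Q, G, _cross_entropy(F, Q @ G, held), np.asarray(path), converged)


def _cross_entropy(F, P, mask) -> float:
    """Binomial cross-entropy of held-out frequencies F against predictions P."""
    p = np.clip(P[mask], 1e-6, 1 - 1e-6)
    f = F[mask]
    return float(-(f * np.log(p) + (1 - f) * np.log(1 - p)).mean())


def choose_k(
    g: GenotypeMatrix | np.ndarray,
    k_range=range(1, 12),
    holdout_fraction: float = 0.05,
    seed: int = 0,
    elbow_tol: float = 0.02,
) -> tuple[int, pd.Series]:
    """Elbow selection of the number of ancestral clusters.

    Fits :func:`fit_ancestry` for each K and returns the K at which the
    masked cross-entropy stops improving by more than ``elbow_tol`` of the
    total decline over the K range (steep decline, then marginal gains), plus
    the full cross-entropy path. The absolute cross-entropy carries a large
    irreducible binomial-noise floor, so the elbow is judged on the decline,
    not the raw value.
    """
    ks = list(k_range)
    ce = {}
    for K in ks:
        ce[K] = fit_ancestry(g, K, seed=seed, holdout_fraction=holdout_fraction).cross_entropy
    series = pd.Series(ce, name="cross_entropy")
    total_drop = max(ce[ks[0]] - min(ce.values()), 1e-12)
    for a, b in zip(ks, ks[1:]):
        if (ce[a] - ce[b]) <= elbow_tol * total_drop:
            return a, series
    return ks[int(np.argmin(series.to_numpy()))], series
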