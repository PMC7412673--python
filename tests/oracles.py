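"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own optimization and linear-algebra
paths: likelihoods are maximized by dense grid search with local zoom, and
embedding variances come from a Gram-matrix eigendecomposition.
"""
from __future__ import annotations

import numpy as np
from scipy import stats


def _compress(x):
    vals, cnt = np.unique(np.asarray(x, dtype=np.int64), return_counts=True)
    return vals.astype(float), cnt.astype(float)


def nb_grid_loglik(x, n_grid: int = 400, zooms: int = 3) -> float:
    """Best NB log-likelihood with mean fixed at the sample mean, r by grid search."""
    vals, w = _compress(x)
    lam = float(np.mean(x))
    best_ll, best_r = -np.inf, 1.0
    lo, hi = 1e-3, 1e6
    for _ in range(zooms + 1):
        rs = np.geomspace(lo, hi, n_grid)
        ll = stats.nbinom.logpmf(vals[None, :], rs[:, None], rs[:, None] / (rs[:, None] + lam)) @ w
        i = int(np.argmax(ll))
        if ll[i] > best_ll:
            best_ll, best_r = float(ll[i]), rs[i]
        lo, hi = rs[max(i - 1, 0)], rs[min(i + 1, n_grid - 1)]
    pois = float(stats.poisson.logpmf(vals, lam) @ w)
    return max(best_ll, pois)


def zinb_grid_loglik(x, n_grid: int = 30, zooms: int = 4) -> float:
    """Best ZINB log-likelihood by 3-d grid search over (lambda, r, pi0) with zoom."""
    vals, w = _compress(x)
    zero = vals == 0
    mean = float(np.mean(x))
    lam_lo, lam_hi = max(mean, 1e-3) * 0.5, max(np.max(x), mean, 1.0) * 5.0
    r_lo, r_hi = 1e-3, 1e6
    p_lo, p_hi = 0.0, 1.0 - 1e-6
    best = (-np.inf, mean, 1.0, 0.0)
    for _ in range(zooms + 1):
        lams = np.geomspace(lam_lo, lam_hi, n_grid)
        rs = np.geomspace(r_lo, r_hi, n_grid)
        pis = np.linspace(p_lo, p_hi, n_grid)
        # nb logpmf over (lam, r, value)
        L = lams[:, None, None]
        R = rs[None, :, None]
        nb = stats.nbinom.logpmf(vals[None, None, :], R, R / (R + L))
        for pi0 in pis:
            with np.errstate(divide="ignore"):
                contrib = np.where(
                    zero[None, None, :],
                    np.log(pi0 + (1 - pi0) * np.exp(nb)),
                    np.log1p(-pi0) + nb,
                )
            ll = contrib @ w
            i, j = np.unravel_index(np.argmax(ll), ll.shape)
            if ll[i, j] > best[0]:
                best = (float(ll[i, j]), lams[i], rs[j], pi0)
        _, bl, br, bp = best
        lam_lo, lam_hi = bl / 1.6, bl * 1.6
        r_lo, r_hi = br / 2.5, br * 2.5
        span = (p_hi - p_lo) / 6
        p_lo, p_hi = max(bp - span, 0.0), min(bp + span, 1.0 - 1e-6)
    return max(best[0], nb_grid_loglik(x))


def gram_embedding_variance(counts_cells_by_features: np.ndarray, n_pc: int) -> float:
    """Sum of sample variances of uncentered-PCA embeddings via the Gram matrix."""
    y = np.log1p(np.asarray(counts_cells_by_features, dtype=float))
    if y.shape[0] < 2:
        return 0.0
    gram = y @ y.T
    evals, evecs = np.linalg.eigh(gram)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.clip(evals[order], 0, None), evecs[:, order]
    emb = evecs * np.sqrt(evals)  # U * S
    k = min(n_pc, emb.shape[1])
    return float(emb[:, :k].var(axis=0, ddof=1).sum())
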