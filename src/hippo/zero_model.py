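"""Per-gene zero-proportion statistics and count-model diagnostics.

For each gene g with counts X_g1..X_gC the observed zero proportion is
p_hat = #{c : X_gc = 0}/C and the expected zero proportion under a
homogeneous Poisson model is exp(-mean).  Cell-type heterogeneity inflates
the observed zeros above the Poisson expectation (a finite Poisson mixture
has zero probability sum_k pi_k exp(-lambda_k) >= exp(-sum_k pi_k lambda_k)
by Jensen's inequality), so a one-sided z test on p_hat - exp(-mean) flags
heterogeneous genes.  The module also provides the Poisson deviance as an
overdispersion-sensitive alternative feature score, and maximum-likelihood
fits of the Poisson, negative binomial (NB) and zero-inflated negative
binomial (ZINB) models with nested likelihood-ratio tests, used to diagnose
whether counts need anything beyond a Poisson.

Parameterization: the NB dispersion r is defined through
variance = lambda^2/r + lambda, so r -> infinity recovers the Poisson.
The ZINB is pi0 * delta_0 + (1 - pi0) * NB(lambda, r).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import optimize, special
from scipy import stats as sps

from .counts import CountMatrix, ValidationError

__all__ = [
    "GeneZeroStats",
    "ModelFit",
    "LRTResult",
    "gene_zero_stats",
    "deviance_statistic",
    "select_features",
    "fit_poisson",
    "fit_nb",
    "fit_zinb",
    "lrt",
    "expected_zero",
    "model_variance",
    "zero_stats_frame",
    "write_zero_stats",
]

R_MAX = 1e6  # NB dispersion sentinel for the Poisson boundary
R_MIN = 1e-3


@dataclass
class GeneZeroStats:
    """Zero-proportion summary for one gene across C cells."""

    gene_id: str
    mean: float          # lambda_hat, UMI counts per cell
    zero_prop: float     # observed p_hat in [0, 1]
    expected_zero: float # exp(-mean)
    z: float             # zero-inflation statistic; 0 when p_hat is 0 or 1
    deviance: float      # Poisson deviance d_g >= 0
    n_cells: int


@dataclass
class ModelFit:
    """Maximum-likelihood fit of one count model to one gene's counts."""

    model: Literal["poisson", "nb", "zinb"]
    lam: float
    loglik: float
    n_params: int
    r: float | None = None
    pi0: float | None = None
    converged: bool = True


@dataclass
class LRTResult:
    """Likelihood-ratio test between two nested count models (df = 1)."""

    null_model: str
    alt_model: str
    stat: float
    df: int
    p_value: float


# ---------------------------------------------------------------------------
# zero-proportion statistics


def gene_zero_stats(
    m: CountMatrix, se: Literal["observed", "null"] = "observed"
) -> list[GeneZeroStats]:
    """Per-gene mean, zero proportion, Poisson-expected zero, z and deviance.

    z = (p_hat - exp(-mean)) / sqrt(v/C) where v is p_hat(1-p_hat) for
    ``se="observed"`` (default) or exp(-mean)(1-exp(-mean)) for
    ``se="null"``.  Genes with p_hat in {0, 1} (so the observed-variance
    standard error is 0) get z = 0 by convention: an all-zero gene has a
    zero numerator as well, and a gene with no zeros cannot be zero-inflated.
    """
    if m.n_genes == 0 or m.n_cells == 0:
        raise ValidationError("empty count matrix")
    if m.n_cells < 2:
        raise ValidationError("need at least 2 cells")
    C = m.n_cells
    v = m.values
    means = np.asarray(v.sum(axis=1)).ravel() / C
    nnz = np.diff(v.indptr)
    zero_prop = 1.0 - nnz / C
    expected = np.exp(-means)
    if se == "observed":
        var = zero_prop * (1.0 - zero_prop)
    elif se == "null":
        var = expected * (1.0 - expected)
    else:
        raise ValueError(f"unknown se mode {se!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (zero_prop - expected) / np.sqrt(var / C)
    z[~np.isfinite(z)] = 0.0
    dev = _deviance_rows(v, means)
    return [
        GeneZeroStats(m.gene_ids[g], float(means[g]), float(zero_prop[g]),
                      float(expected[g]), float(z[g]), float(dev[g]), C)
        for g in range(m.n_genes)
    ]


def _deviance_rows(v: sp.csr_matrix, means: np.ndarray) -> np.ndarray:
    """Row-wise Poisson deviance 2*sum(x*log(x/mean) - (x - mean)), 0log0 = 0.

    The linear term sums to zero exactly when mean is the row mean, but is
    kept so the formula stays valid for externally supplied means.
    """
    C = v.shape[1]
    x = v.data
    rows = np.repeat(np.arange(v.shape[0]), np.diff(v.indptr))
    dev = np.zeros(v.shape[0])
    pos = means > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        term = x * (np.log(x) - np.log(means[rows]))
    np.add.at(dev, rows, term)
    np.add.at(dev, rows, -(x - means[rows]))          # nonzero entries
    dev -= (C - np.diff(v.indptr)) * (0.0 - means)    # zero entries: -(0 - mean)
    dev[~pos] = 0.0
    return np.maximum(2.0 * dev, 0.0)


def deviance_statistic(counts: Sequence[float] | np.ndarray) -> float:
    """Poisson deviance of one gene: twice the saturated-minus-fitted loglik gap."""
    x = np.asarray(counts, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValidationError("need a 1-d vector of length >= 2")
    mean = x.mean()
    if mean == 0:
        return 0.0
    pos = x > 0
    s = float(np.sum(x[pos] * np.log(x[pos] / mean))) - float(np.sum(x - mean))
    return max(2.0 * s, 0.0)


def select_features(
    stats: Sequence[GeneZeroStats],
    method: Literal["zero_inflation", "deviance"] = "zero_inflation",
    z_threshold: float = 2.0,
    deviance_threshold: float | None = None,
) -> np.ndarray:
    """Indices of genes whose statistic strictly exceeds the threshold.

    Ordered by descending statistic (ties keep input order).  The strict
    inequality matches the one-sided alternative p > exp(-lambda).
    """
    if method == "zero_inflation":
        vals = np.array([s.z for s in stats])
        thr = z_threshold
    elif method == "deviance":
        if deviance_threshold is None:
            raise ValueError("deviance method requires deviance_threshold")
        vals = np.array([s.deviance for s in stats])
        thr = deviance_threshold
    else:
        raise ValueError(f"unknown selection method {method!r}")
    if not np.isfinite(thr):
        raise ValueError("threshold must be finite")
    idx = np.flatnonzero(vals > thr)
    return idx[np.argsort(-vals[idx], kind="stable")]


# ---------------------------------------------------------------------------
# Poisson / NB / ZINB maximum likelihood


def _compress(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    vals, cnt = np.unique(np.asarray(x, dtype=np.int64), return_counts=True)
    return vals.astype(float), cnt.astype(float)


def _poisson_loglik(vals: np.ndarray, wts: np.ndarray, lam: float) -> float:
    if lam == 0:
        return 0.0 if vals.max(initial=0) == 0 else -np.inf
    ll = vals * math.log(lam) - lam - special.gammaln(vals + 1.0)
    return float(np.dot(wts, ll))


def _nb_loglik(vals: np.ndarray, wts: np.ndarray, lam: float, r: float) -> float:
    # NB with mean lam, variance lam^2/r + lam <=> nbinom(n=r, p=r/(r+lam))
    if lam == 0:
        return 0.0 if vals.max(initial=0) == 0 else -np.inf
    p = r / (r + lam)
    ll = sps.nbinom.logpmf(vals, r, p)
    return float(np.dot(wts, ll))


def _zinb_loglik(vals: np.ndarray, wts: np.ndarray, lam: float, r: float, pi0: float) -> float:
    p = r / (r + lam)
    nb = sps.nbinom.logpmf(vals, r, p)
    zero = vals == 0
    out = np.empty_like(nb)
    with np.errstate(divide="ignore"):
        out[zero] = np.log(pi0 + (1.0 - pi0) * np.exp(nb[zero]))
        out[~zero] = math.log1p(-pi0) + nb[~zero] if pi0 < 1 else -np.inf
    return float(np.dot(wts, out))


def fit_poisson(counts: Sequence[float] | np.ndarray) -> ModelFit:
    """Closed-form Poisson MLE: lambda = sample mean."""
    x = np.asarray(counts, dtype=float)
    if x.size < 1:
        raise ValidationError("empty vector")
    vals, wts = _compress(x)
    lam = float(x.mean())
    return ModelFit("poisson", lam, _poisson_loglik(vals, wts, lam), 1)


def fit_nb(counts: Sequence[float] | np.ndarray) -> ModelFit:
    """NB fit with lambda fixed at the sample mean and r optimized on a log scale.

    When the sample variance does not exceed the mean there is no
    overdispersion to estimate and the fit sits on the Poisson boundary
    (r = 1e6 sentinel, Poisson log-likelihood).
    """
    x = np.asarray(counts, dtype=float)
    if x.size < 2:
        raise ValidationError("need >= 2 observations")
    vals, wts = _compress(x)
    lam = float(x.mean())
    pois_ll = _poisson_loglik(vals, wts, lam)
    boundary = ModelFit("nb", lam, pois_ll, 2, r=R_MAX)
    if lam == 0 or x.var() <= lam:
        return boundary
    res = optimize.minimize_scalar(
        lambda logr: -_nb_loglik(vals, wts, lam, math.exp(logr)),
        bounds=(math.log(R_MIN), math.log(R_MAX)),
        method="bounded",
        options={"xatol": 1e-8},
    )
    r_hat = math.exp(res.x)
    ll = -res.fun
    if ll < pois_ll:  # optimizer worse than the boundary: report the boundary
        return boundary
    return ModelFit("nb", lam, ll, 2, r=r_hat, converged=bool(res.success))


def fit_zinb(counts: Sequence[float] | np.ndarray, max_iter: int = 500, tol: float = 1e-8) -> ModelFit:
    """ZINB fit by coordinate ascent over (pi0, lambda, r), seeded at the NB fit.

    lambda is the mean of the NB component, not the marginal mean.  With no
    zeros in the data pi0 = 0 and the result equals the NB fit.
    """
    x = np.asarray(counts, dtype=float)
    if x.size < 2:
        raise ValidationError("need >= 2 observations")
    nb = fit_nb(x)
    if not np.any(x == 0) or nb.lam == 0:
        return ModelFit("zinb", nb.lam, nb.loglik, 3, r=nb.r, pi0=0.0, converged=nb.converged)
    vals, wts = _compress(x)
    lam, r, pi0 = nb.lam, float(nb.r), 0.0
    lam_hi = max(x.max() * 10.0, lam * 10.0, 1.0)
    ll = _zinb_loglik(vals, wts, lam, r, pi0)
    converged = False
    for _ in range(max_iter):
        res = optimize.minimize_scalar(
            lambda p: -_zinb_loglik(vals, wts, lam, r, p),
            bounds=(0.0, 1.0 - 1e-9), method="bounded", options={"xatol": 1e-10},
        )
        if -res.fun >= ll:
            pi0 = float(res.x)
        res = optimize.minimize_scalar(
            lambda lg: -_zinb_loglik(vals, wts, math.exp(lg), r, pi0),
            bounds=(math.log(max(lam * 1e-3, 1e-9)), math.log(lam_hi)),
            method="bounded", options={"xatol": 1e-10},
        )
        if -res.fun >= ll:
            lam = math.exp(res.x)
        res = optimize.minimize_scalar(
            lambda lr: -_zinb_loglik(vals, wts, lam, math.exp(lr), pi0),
            bounds=(math.log(R_MIN), math.log(R_MAX)), method="bounded",
            options={"xatol": 1e-10},
        )
        if -res.fun >= ll:
            r = math.exp(res.x)
        new_ll = _zinb_loglik(vals, wts, lam, r, pi0)
        if new_ll - ll < tol:
            ll = max(new_ll, ll)
            converged = True
            break
        ll = new_ll
    if ll < nb.loglik:  # never report worse than the nested NB optimum
        return ModelFit("zinb", nb.lam, nb.loglik, 3, r=nb.r, pi0=0.0, converged=converged)
    return ModelFit("zinb", lam, ll, 3, r=r, pi0=pi0, converged=converged)


_NESTED = {("poisson", "nb"), ("nb", "zinb")}


def lrt(null_fit: ModelFit, alt_fit: ModelFit) -> LRTResult:
    """Likelihood-ratio test of two nested fits, stat ~ chi^2 with 1 df.

    The statistic is clamped at zero (boundary fits can tie the null).
    """
    if (null_fit.model, alt_fit.model) not in _NESTED:
        raise ValueError(f"{null_fit.model} is not nested in {alt_fit.model}")
    stat = max(0.0, 2.0 * (alt_fit.loglik - null_fit.loglik))
    return LRTResult(null_fit.model, alt_fit.model, stat, 1, float(sps.chi2.sf(stat, 1)))


# ---------------------------------------------------------------------------
# closed-form zero probabilities and variances


def expected_zero(
    model: str,
    lam: float | None = None,
    r: float | None = None,
    pi0: float | None = None,
    weights: Sequence[float] | None = None,
    lambdas: Sequence[float] | None = None,
) -> float:
    """Zero probability under a named count model.

    poisson: exp(-lam); nb: (r/(r+lam))^r;
    zinb: pi0 + (1-pi0)(r/(r+lam))^r; mixture: sum_k pi_k exp(-lam_k).
    """
    if model == "poisson":
        return math.exp(-_req(lam, "lam"))
    if model == "nb":
        lam, r = _req(lam, "lam"), _req(r, "r")
        return (r / (r + lam)) ** r
    if model == "zinb":
        lam, r, pi0 = _req(lam, "lam"), _req(r, "r"), _req(pi0, "pi0")
        return pi0 + (1.0 - pi0) * (r / (r + lam)) ** r
    if model == "mixture":
        w, lams = _mixture_params(weights, lambdas)
        return float(np.dot(w, np.exp(-lams)))
    raise ValueError(f"unknown model {model!r}")


def model_variance(
    model: str,
    lam: float | None = None,
    r: float | None = None,
    pi0: float | None = None,
    weights: Sequence[float] | None = None,
    lambdas: Sequence[float] | None = None,
) -> float:
    """Count variance under the heterogeneity-alternative form of each model.

    mixture: sum pi_k (lam_k + lam_k^2) - (sum pi_k lam_k)^2;
    nb: lam^2/r + lam; zinb: (1-pi0)^2 (lam^2/r + lam);
    poisson (the null): lam.
    """
    if model == "poisson":
        return _req(lam, "lam")
    if model == "nb":
        lam, r = _req(lam, "lam"), _req(r, "r")
        return lam * lam / r + lam
    if model == "zinb":
        lam, r, pi0 = _req(lam, "lam"), _req(r, "r"), _req(pi0, "pi0")
        return (1.0 - pi0) ** 2 * (lam * lam / r + lam)
    if model == "mixture":
        w, lams = _mixture_params(weights, lambdas)
        return float(np.dot(w, lams + lams**2) - np.dot(w, lams) ** 2)
    raise ValueError(f"unknown model {model!r}")


def _req(v: float | None, name: str) -> float:
    if v is None:
        raise ValueError(f"parameter {name} is required")
    return float(v)


def _mixture_params(weights, lambdas) -> tuple[np.ndarray, np.ndarray]:
    if weights is None or lambdas is None:
        raise ValueError("mixture model requires weights and lambdas")
    w = np.asarray(weights, dtype=float)
    lams = np.asarray(lambdas, dtype=float)
    if w.shape != lams.shape:
        raise ValidationError("weights and lambdas must have the same length")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValidationError("mixture weights must sum to 1")
    if np.any(w < 0) or np.any(lams < 0):
        raise ValidationError("weights and rates must be nonnegative")
    return w, lams


# ---------------------------------------------------------------------------
# tabular export


def zero_stats_frame(stats: Sequence[GeneZeroStats]) -> pd.DataFrame:
    """Statistics table with one-sided normal p and Bonferroni adjustment."""
    df = pd.DataFrame(
        {
            "gene_id": [s.gene_id for s in stats],
            "n_cells": [s.n_cells for s in stats],
            "mean": [s.mean for s in stats],
            "zero_prop": [s.zero_prop for s in stats],
            "expected_zero": [s.expected_zero for s in stats],
            "z": [s.z for s in stats],
            "deviance": [s.deviance for s in stats],
        }
    )
    df["p_value"] = sps.norm.sf(df["z"].to_numpy())
    df["p_bonferroni"] = np.minimum(df["p_value"] * len(df), 1.0)
    return df


def write_zero_stats(stats: Sequence[GeneZeroStats], path: str | Path) -> None:
    zero_stats_frame(stats).to_csv(path, sep="\t", index=False)
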