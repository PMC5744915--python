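"""Phylogenetic comparative statistics on shape data.

Four pieces of machinery:

* ``kmult`` — multivariate phylogenetic signal (Blomberg's K generalized to
  high-dimensional shape data): the ratio of tip variation around the
  phylogenetic (GLS) mean to phylogenetically transformed variation,
  divided by its Brownian-motion expectation on the tree, so K ~ 1 under
  BM and K < 1 when relatives resemble each other less than BM predicts.
  Significance by permuting taxa across tips.
* ``procrustes_variance`` / ``disparity_test`` — morphological disparity as
  Procrustes variance (mean squared distance of group members from the
  group mean shape, divisor n) with a group-label permutation test.
* ``compare_evolutionary_rates`` — per-group multivariate Brownian rates
  (sigma^2_mult) from phylogenetically transformed residuals, with the
  observed max/min rate ratio tested against datasets simulated under a
  single common rate.
* ``fit_evolutionary_models`` — ML fits of Brownian motion (BM), white
  noise (WN), Ornstein-Uhlenbeck (OU, fixed-root convention) and early
  burst (EB) to a single trait (one PC at a time), ranked by AICc.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .phylo import TimeTree, bm_simulate, _tip_matrix
from .shapes import AlignedShapes

__all__ = [
    "KResult",
    "DisparityResult",
    "RateResult",
    "ModelFit",
    "ModelFitTable",
    "kmult",
    "procrustes_variance",
    "disparity_test",
    "compare_evolutionary_rates",
    "fit_evolutionary_models",
    "aicc",
]

MODELS = ("BM", "WN", "OU", "EB")


# ---------------------------------------------------------------------------
# result containers


@dataclass
class KResult:
    K: float
    p: float
    n_permutations: int
    seed: int | None

    def to_dict(self) -> dict:
        return {"K": self.K, "p": self.p,
                "n_permutations": self.n_permutations, "seed": self.seed}


@dataclass
class DisparityResult:
    variances: dict[str, float]
    fold_difference: float
    p: float
    n_permutations: int
    seed: int | None

    def to_dict(self) -> dict:
        return {"variances": self.variances, "fold_difference": self.fold_difference,
                "p": self.p, "n_permutations": self.n_permutations, "seed": self.seed}


@dataclass
class RateResult:
    rates: dict[str, float]
    fold_difference: float
    p: float
    n_sims: int
    seed: int | None

    def to_dict(self) -> dict:
        return {"rates": self.rates, "fold_difference": self.fold_difference,
                "p": self.p, "n_sims": self.n_sims, "seed": self.seed}


@dataclass
class ModelFit:
    model: str
    log_likelihood: float
    params: dict[str, float]
    k_params: int
    aicc: float
    converged: bool = True
    daicc: float = float("nan")


@dataclass
class ModelFitTable:
    fits: dict[str, ModelFit] = field(default_factory=dict)
    n: int = 0

    def __post_init__(self) -> None:
        self._rank()

    def _rank(self) -> None:
        if not self.fits:
            return
        best = min(f.aicc for f in self.fits.values())
        for f in self.fits.values():
            f.daicc = f.aicc - best

    @property
    def best_model(self) -> str:
        return min(self.fits, key=lambda m: self.fits[m].aicc)

    def to_frame(self):
        import pandas as pd

        rows = []
        for m in MODELS:
            if m not in self.fits:
                continue
            f = self.fits[m]
            rows.append({"model": m, "lnL": f.log_likelihood, "k": f.k_params,
                         "AICc": f.aicc, "dAICc": f.daicc,
                         "converged": f.converged, **f.params})
        return pd.DataFrame(rows).set_index("model")


# ---------------------------------------------------------------------------
# phylogenetic signal


def _as_matrix(data, tree: TimeTree, taxa: Sequence[str] | None):
    """Coerce data to (n, p) in a definite taxon order matching the tree."""
    if isinstance(data, AlignedShapes):
        taxa = data.taxa
        Y = data.flat()
    elif isinstance(data, Mapping):
        taxa = tree.tip_labels
        Y = _tip_matrix(tree, data)
    else:
        Y = np.asarray(data, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        if taxa is None:
            taxa = tree.tip_labels
    taxa = list(taxa)
    if len(set(taxa)) != len(taxa):
        raise ValueError("duplicate taxa in data")
    missing = set(taxa) ^ set(tree.tip_labels)
    if missing:
        raise ValueError(f"taxon mismatch between data and tree: {sorted(missing)}")
    return Y, taxa


def _k_statistic(Y: np.ndarray, Cinv: np.ndarray, w: np.ndarray,
                 wsum: float, expected: float) -> float:
    a = (w @ Y) / wsum  # GLS phylogenetic mean, shape (p,)
    R = Y - a
    num = float(np.sum(R * R))
    den = float(np.sum(R * (Cinv @ R)))
    return (num / den) / expected


def kmult(data, tree: TimeTree, taxa: Sequence[str] | None = None,
          n_perm: int = 10000, seed: int | None = None) -> KResult:
    """Multivariate phylogenetic signal with a permutation test.

    ``data`` is an :class:`AlignedShapes`, a taxon->vector mapping, or an
    ``(n, p)`` array (then ``taxa`` gives row order; default tree order).
    For p = 1 this reduces exactly to Blomberg's K. The p-value counts
    permutations with K >= observed, using (count + 1) / (n_perm + 1).
    """
    Y, taxa = _as_matrix(data, tree, taxa)
    n = Y.shape[0]
    C = tree.vcv(taxa)
    Cinv = np.linalg.inv(C)
    w = Cinv @ np.ones(n)
    wsum = float(w.sum())
    expected = (np.trace(C) - n / wsum) / (n - 1)
    K_obs = _k_statistic(Y, Cinv, w, wsum, expected)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if _k_statistic(Y[perm], Cinv, w, wsum, expected) >= K_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return KResult(K=float(K_obs), p=float(p), n_permutations=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# disparity


def procrustes_variance(group) -> float:
    """Mean squared Procrustes distance of group members from the group mean.

    Equals the sum of coordinate-wise variances (divisor n).
    """
    if isinstance(group, AlignedShapes):
        X = group.flat()
    else:
        X = np.asarray(group, dtype=float)
        if X.ndim == 3:
            X = X.reshape(X.shape[0], -1)
    if X.shape[0] < 1:
        raise ValueError("empty group")
    return float(np.sum(X.var(axis=0, ddof=0)))


def _group_arrays(aligned, groups: Mapping[str, str], taxa=None):
    if isinstance(aligned, AlignedShapes):
        X = aligned.flat()
        taxa = aligned.taxa
    else:
        X = np.asarray(aligned, dtype=float)
        if X.ndim == 3:
            X = X.reshape(X.shape[0], -1)
        if taxa is None:
            raise ValueError("taxa required for array input")
    labels = []
    for t in taxa:
        if t not in groups:
            raise KeyError(f"no group label for taxon {t!r}")
        labels.append(groups[t])
    return X, np.asarray(labels)


def _group_variances(X: np.ndarray, labels: np.ndarray,
                     names: np.ndarray) -> np.ndarray:
    return np.array([procrustes_variance(X[labels == g]) for g in names])


def disparity_test(aligned, groups: Mapping[str, str], n_perm: int = 1000,
                   seed: int | None = None, taxa=None) -> DisparityResult:
    """Group Procrustes variances and a label-permutation test.

    The test statistic is the maximum absolute pairwise variance
    difference; p counts permuted statistics >= observed with the
    (count + 1)/(n_perm + 1) estimator.
    """
    X, labels = _group_arrays(aligned, groups, taxa)
    names = np.unique(labels)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    for g in names:
        if np.sum(labels == g) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 members")
    v = _group_variances(X, labels, names)
    obs = v.max() - v.min() if len(names) > 2 else abs(v[0] - v[1])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm_labels = labels[rng.permutation(len(labels))]
        pv = _group_variances(X, perm_labels, names)
        stat = pv.max() - pv.min() if len(names) > 2 else abs(pv[0] - pv[1])
        if stat >= obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    fold = float(v.max() / v.min())
    return DisparityResult(variances=dict(zip(names.tolist(), v.tolist())),
                           fold_difference=fold, p=float(p),
                           n_permutations=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# evolutionary rates


def _sigma_mult(X: np.ndarray, labels: np.ndarray, names: np.ndarray,
                p_traits: int) -> np.ndarray:
    """Per-group rates from phylogenetically transformed residuals X."""
    sq = np.sum(X * X, axis=1)
    return np.array(
        [sq[labels == g].sum() / (np.sum(labels == g) * p_traits) for g in names]
    )


def compare_evolutionary_rates(tree: TimeTree, data, groups: Mapping[str, str],
                               n_sims: int = 1000, seed: int | None = None,
                               taxa=None) -> RateResult:
    """Multivariate Brownian rate (sigma^2_mult) per group, with a
    common-rate simulation test on the max/min ratio.

    Residuals from the GLS root estimate are whitened with the inverse
    square root of the tree covariance; each group's rate is its mean
    squared whitened residual per trait dimension. Null datasets are
    simulated under BM with the pooled single rate; p = (count of
    simulated ratios >= observed + 1) / (n_sims + 1).
    """
    Y, taxa_order = _as_matrix(data, tree, taxa)
    labels = np.asarray([groups[t] for t in taxa_order])
    names = np.unique(labels)
    for g in names:
        if np.sum(labels == g) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 tips")
    n, p = Y.shape
    C = tree.vcv(taxa_order)
    eigval, eigvec = np.linalg.eigh(C)
    inv_sqrt = eigvec @ np.diag(1.0 / np.sqrt(eigval)) @ eigvec.T
    chol = np.linalg.cholesky(C)
    Cinv = inv_sqrt @ inv_sqrt
    w = Cinv @ np.ones(n)
    wsum = w.sum()

    def rates_of(Ymat: np.ndarray) -> np.ndarray:
        a = (w @ Ymat) / wsum
        X = inv_sqrt @ (Ymat - a)
        return _sigma_mult(X, labels, names, p)

    obs_rates = rates_of(Y)
    obs_ratio = obs_rates.max() / obs_rates.min()
    # null rate: single-rate sigma^2_mult pooled over all tips
    a = (w @ Y) / wsum
    Xall = inv_sqrt @ (Y - a)
    pooled = float(np.sum(Xall * Xall) / (n * p))
    rng = np.random.default_rng(seed)
    count = 0
    sigma = np.sqrt(pooled)
    for _ in range(n_sims):
        Ysim = sigma * (chol @ rng.standard_normal((n, p)))
        r = rates_of(Ysim)
        if r.max() / r.min() >= obs_ratio:
            count += 1
    p_val = (count + 1) / (n_sims + 1)
    return RateResult(rates=dict(zip(names.tolist(), obs_rates.tolist())),
                      fold_difference=float(obs_ratio), p=float(p_val),
                      n_sims=n_sims, seed=seed)


# ---------------------------------------------------------------------------
# model selection


def aicc(lnL: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike information criterion."""
    if n - k - 1 <= 0:
        return float("inf")
    return -2.0 * lnL + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _profile_loglik(R: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Profile ML over z0 and sigma^2 for covariance sigma^2 * R.

    Returns (lnL, sigma2_hat, z0_hat); z0 is the GLS mean under R.
    """
    n = len(y)
    L = np.linalg.cholesky(R)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    ones = np.ones(n)
    from scipy.linalg import solve_triangular

    u = solve_triangular(L, y, lower=True)
    v = solve_triangular(L, ones, lower=True)
    z0 = float(v @ u / (v @ v))
    r = u - z0 * v
    sigma2 = float(r @ r) / n
    lnL = -0.5 * (n * np.log(2.0 * np.pi) + n * np.log(sigma2) + logdet + n)
    return float(lnL), sigma2, z0


def fit_evolutionary_models(tree: TimeTree, trait, models: Sequence[str] = MODELS,
                            taxa=None) -> ModelFitTable:
    """ML fits of BM, WN, OU and EB to one continuous trait, ranked by AICc.

    All models are Gaussian with a single ancestral mean z0 and rate
    sigma^2, both profiled out analytically; OU's selection strength alpha
    and EB's rate-decay r are optimized numerically within
    [1e-8, 50]/depth and [-10, 0]/depth respectively. OU uses the
    fixed-root convention (process starts at z0 = theta at the root),
    which requires an ultrametric tree.
    """
    y_mat, taxa_order = _as_matrix(trait, tree, taxa)
    if y_mat.shape[1] != 1:
        raise ValueError("fit_evolutionary_models takes a single trait (one PC)")
    y = y_mat[:, 0]
    n = len(y)
    if n < 5:
        raise ValueError("need at least 5 tips for model fitting")
    C = tree.vcv(taxa_order)
    T = tree.depth
    fits: dict[str, ModelFit] = {}

    if "BM" in models:
        lnL, s2, z0 = _profile_loglik(C, y)
        fits["BM"] = ModelFit("BM", lnL, {"sigma2": s2, "z0": z0}, 2, aicc(lnL, 2, n))

    if "WN" in models:
        lnL, s2, z0 = _profile_loglik(np.eye(n), y)
        fits["WN"] = ModelFit("WN", lnL, {"sigma2": s2, "mean": z0}, 2,
                              aicc(lnL, 2, n))

    if "OU" in models:
        if not tree.is_ultrametric():
            raise ValueError("OU fitting requires an ultrametric tree")
        tipd = np.diag(C)
        D = tipd[:, None] + tipd[None, :] - 2.0 * C  # patristic distances

        def ou_corr(alpha: float) -> np.ndarray:
            # fixed-root OU covariance divided by sigma^2
            return np.exp(-alpha * D) * (1.0 - np.exp(-2.0 * alpha * C)) / (2.0 * alpha)

        def neg_ou(log_alpha: float) -> float:
            return -_profile_loglik(ou_corr(np.exp(log_alpha)), y)[0]

        lo, hi = np.log(1e-8 / T), np.log(50.0 / T)
        res = minimize_scalar(neg_ou, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-10})
        alpha = float(np.exp(res.x))
        lnL, s2, z0 = _profile_loglik(ou_corr(alpha), y)
        fits["OU"] = ModelFit("OU", lnL,
                              {"sigma2": s2, "alpha": alpha, "theta": z0, "z0": z0},
                              3, aicc(lnL, 3, n), converged=bool(res.success))

    if "EB" in models:
        def eb_corr(r: float) -> np.ndarray:
            if abs(r) < 1e-12:
                return C
            return np.expm1(r * C) / r

        def neg_eb(r: float) -> float:
            return -_profile_loglik(eb_corr(r), y)[0]

        res = minimize_scalar(neg_eb, bounds=(-10.0 / T, 0.0), method="bounded",
                              options={"xatol": 1e-12})
        r_hat = float(min(res.x, 0.0))
        lnL, s2, z0 = _profile_loglik(eb_corr(r_hat), y)
        # the boundary r = 0 (pure BM) may beat the interior optimum
        lnL0, s20, z00 = _profile_loglik(C, y)
        if lnL0 > lnL:
            lnL, s2, z0, r_hat = lnL0, s20, z00, 0.0
        fits["EB"] = ModelFit("EB", lnL, {"sigma2": s2, "r": r_hat, "z0": z0},
                              3, aicc(lnL, 3, n), converged=bool(res.success))

    return ModelFitTable(fits=fits, n=n)
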