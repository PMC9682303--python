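"""Evolutionary rate comparison.

* :func:`module_rate_ratio_test` — multivariate Brownian-motion rate per
  module, max/min ratio tested against single-rate BM simulation.
* :func:`multirate_bm` — penalized-likelihood variable-rate BM for a scalar
  trait: the log rate itself evolves by BM on the tree, with a smoothing
  coefficient lambda weighting that penalty against the data likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .io import ModuleMap
from .phylo import _inv_sqrt, gls_mean, perm_pvalue, phylo_vcv
from .tree import Phylogeny

__all__ = ["RateResult", "module_rate_ratio_test",
           "MultirateBMResult", "multirate_bm"]


@dataclass
class RateResult:
    sigma2_per_module: dict[str, float]
    ratio: float
    p: float
    null_distribution: np.ndarray
    n_sim: int


def _module_sigma2(X: np.ndarray, cols: list[np.ndarray]) -> np.ndarray:
    n = X.shape[0]
    return np.array([float((X[:, c] ** 2).sum()) / (n * c.size) for c in cols])


def module_rate_ratio_test(data: np.ndarray, partition: ModuleMap,
                           tree: Phylogeny, n_sim: int = 1000, d: int = 2,
                           rng=None, taxa: list[str] | None = None) -> RateResult:
    """Max/min ratio of per-module multivariate BM rates.

    The per-module rate is the mean squared phylogenetically transformed
    deviation over that module's coordinates.  The null replicates datasets
    under single-rate BM on the tree (common rate = pooled estimate) and
    recomputes the ratio; p = (b+1)/(n_sim+1) for null >= observed.
    """
    if partition.n_modules < 2:
        raise ValueError("need at least 2 modules")
    rng = np.random.default_rng(rng)
    pc = phylo_vcv(tree)
    X = np.asarray(data, float)
    if taxa is not None and list(taxa) != pc.taxa:
        pos = {t: i for i, t in enumerate(taxa)}
        X = X[[pos[t] for t in pc.taxa]]
    Pinv = _inv_sqrt(pc.C)

    def transform(Y):
        return Pinv @ (Y - gls_mean(Y, pc.C))

    Xt = transform(X)
    cols = [partition.columns(m, d) for m in partition.module_names]
    for name, c in zip(partition.module_names, cols):
        if c.size == 0:
            raise ValueError(f"module {name!r} has dimension 0")
    sig = _module_sigma2(Xt, cols)
    obs = float(sig.max() / sig.min())

    p_tot = sum(c.size for c in cols)
    pooled = float((Xt ** 2).sum()) / (Xt.shape[0] * p_tot)
    L = np.linalg.cholesky(pc.C + 1e-12 * np.eye(pc.C.shape[0]))
    null = np.empty(n_sim)
    for b in range(n_sim):
        Ysim = L @ rng.standard_normal((pc.C.shape[0], p_tot)) * np.sqrt(pooled)
        s = _module_sigma2(transform(Ysim), cols)
        null[b] = s.max() / s.min()
    return RateResult(
        sigma2_per_module=dict(zip(partition.module_names, sig.tolist())),
        ratio=obs, p=perm_pvalue(null, obs, "ge"),
        null_distribution=null, n_sim=n_sim)


# ----------------------------------------------------- multirate BM (PL)

@dataclass
class MultirateBMResult:
    log_rates: np.ndarray          # per node, tree node indexing
    rates: np.ndarray
    objective: float
    lam: float
    converged: bool
    single_rate: float


def _descendant_matrix(tree: Phylogeny) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(Z, child_idx, parent_idx): Z[e, a] = 1 if tip a descends through edge e.

    The tip covariance under per-edge rates is then Z' diag(sig2_e * t_e) Z.
    """
    tips = tree.tip_indices
    tip_pos = {t: j for j, t in enumerate(tips)}
    edges = tree.edges()
    Z = np.zeros((len(edges), len(tips)))
    for e, (_, c, _) in enumerate(edges):
        for t in tree.descendant_tips(c):
            Z[e, tip_pos[t]] = 1.0
    child = np.array([c for _, c, _ in edges])
    parent = np.array([p for p, _, _ in edges])
    return Z, child, parent


def _tip_loglik(y: np.ndarray, Z: np.ndarray, weights: np.ndarray) -> float:
    """Log-likelihood of tip values given per-edge variances (GLS mean)."""
    n = y.size
    C = (Z * weights[:, None]).T @ Z
    sign, logdet = np.linalg.slogdet(C)
    if sign <= 0:
        return -np.inf
    Ci = np.linalg.inv(C)
    one = np.ones(n)
    mu = (one @ Ci @ y) / (one @ Ci @ one)
    r = y - mu
    return float(-0.5 * (n * np.log(2 * np.pi) + logdet + r @ Ci @ r))


def multirate_bm(trait: np.ndarray, tree: Phylogeny, lam: float = 1.0,
                 taxa: list[str] | None = None, tol: float = 1e-8,
                 max_iter: int = 500) -> MultirateBMResult:
    """Penalized-likelihood variable-rate BM for one scalar trait.

    Each node carries a log rate; an edge's rate is the average of the rates
    at its endpoints.  The objective is the tip-data log-likelihood plus
    ``lam`` times the log probability density of the node log-rates under BM
    on the same tree (unit variance per unit branch length; a flat prior on
    the root's log rate).  Large ``lam`` therefore pulls all rates to the
    single-rate maximum-likelihood estimate, which is also the start point.
    """
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    y = np.asarray(trait, float).ravel()
    if not np.isfinite(y).all():
        raise ValueError("trait values must be finite")
    if taxa is not None:
        pos = {t: i for i, t in enumerate(taxa)}
        y = y[[pos[t] for t in tree.tip_labels]]
    if y.size != tree.n_tips:
        raise ValueError("one trait value per tip required")

    C = tree.vcv()
    mu0 = gls_mean(y[:, None], C).item()
    r0 = y - mu0
    sig2_single = float(r0 @ np.linalg.solve(C, r0)) / tree.n_tips
    sig2_single = max(sig2_single, 1e-12)

    m = tree.n_nodes
    edges = tree.edges()
    Z, child, parent = _descendant_matrix(tree)
    elen = np.array([max(t, 1e-12) for _, _, t in edges])
    pen_const = float(-0.5 * np.log(2 * np.pi * elen).sum())

    def objective(lr: np.ndarray) -> float:
        sig2 = np.exp(lr)
        weights = 0.5 * (sig2[parent] + sig2[child]) * elen
        ll = _tip_loglik(y, Z, weights)
        pen = pen_const - 0.5 * float(((lr[child] - lr[parent]) ** 2 / elen).sum())
        return -(ll + lam * pen)

    x0 = np.full(m, np.log(sig2_single))
    res = optimize.minimize(objective, x0, method="L-BFGS-B",
                            options={"maxiter": max_iter, "ftol": tol,
                                     "gtol": 1e-6})
    if not np.isfinite(res.fun):
        raise RuntimeError(f"multirate BM failed to converge "
                           f"(last objective {res.fun})")
    lr = res.x
    return MultirateBMResult(log_rates=lr, rates=np.exp(lr),
                             objective=float(-res.fun), lam=lam,
                             converged=bool(res.success),
                             single_rate=sig2_single)
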