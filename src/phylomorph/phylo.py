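"""Brownian-motion machinery shared by the phylogenetically corrected tests.

Everything here assumes trait evolution by single-rate Brownian motion (BM)
on a rooted tree with branch lengths: the expected tip covariance is the
matrix of shared root-to-MRCA path lengths, ancestral states are
generalized-least-squares (GLS) estimates, and "phylogenetic correction"
means pre-multiplying mean-centered data by the inverse square root of that
covariance so the rows become uncorrelated under BM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tree import Phylogeny

__all__ = ["PhyloCovariance", "SignalResult", "phylo_vcv",
           "ancestral_states_bm", "phylo_transform", "TransformedData",
           "gls_mean", "kmult", "perm_pvalue"]


@dataclass
class PhyloCovariance:
    """BM tip covariance C (C[i,j] = depth of MRCA) with its tip order."""

    C: np.ndarray
    taxa: list[str]

    def __post_init__(self):
        self.C = np.asarray(self.C, float)
        n = len(self.taxa)
        if self.C.shape != (n, n):
            raise ValueError("covariance / taxa size mismatch")


@dataclass
class SignalResult:
    """Multivariate phylogenetic signal (Kmult) with its permutation test."""

    K: float
    p: float
    n_perm: int
    null: np.ndarray | None = None


def phylo_vcv(tree: Phylogeny) -> PhyloCovariance:
    """Expected BM covariance among tips (shared path length from root)."""
    if tree.max_depth() <= 0:
        raise ValueError("tree has zero depth")
    return PhyloCovariance(tree.vcv(), tree.tip_labels)


def perm_pvalue(null: np.ndarray, observed: float, tail: str = "ge") -> float:
    """Permutation p-value with the (b+1)/(m+1) estimator (never zero)."""
    null = np.asarray(null, float)
    if tail == "ge":
        b = int(np.sum(null >= observed))
    elif tail == "le":
        b = int(np.sum(null <= observed))
    else:
        raise ValueError("tail must be 'ge' or 'le'")
    return (b + 1) / (null.size + 1)


def _inv(C: np.ndarray) -> np.ndarray:
    return np.linalg.inv(C)


def gls_mean(data: np.ndarray, C: np.ndarray) -> np.ndarray:
    """GLS phylogenetic mean (the BM root-state estimate), per trait."""
    Ci = _inv(C)
    one = np.ones(C.shape[0])
    w = Ci @ one
    return (w @ data) / (one @ w)


def ancestral_states_bm(tree: Phylogeny, tip_values: np.ndarray,
                        taxa: list[str] | None = None) -> dict[int, np.ndarray]:
    """ML (GLS) ancestral state estimates under single-rate BM.

    ``tip_values`` is species x traits in the order of ``taxa`` (defaults to
    ``tree.tip_labels``).  Returns a map internal-node-index -> trait vector;
    the root entry equals the GLS phylogenetic mean.
    """
    Y = np.atleast_2d(np.asarray(tip_values, float))
    if Y.shape[0] == 1 and tree.n_tips > 1:
        Y = Y.T
    order = taxa if taxa is not None else tree.tip_labels
    if len(order) != tree.n_tips or Y.shape[0] != tree.n_tips:
        raise ValueError("tip values must cover every tip exactly once")
    if set(order) != set(tree.tip_labels):
        raise ValueError("taxa do not match the tree's tips")
    # reorder rows to the tree's own tip order
    pos = {t: i for i, t in enumerate(order)}
    Y = Y[[pos[t] for t in tree.tip_labels]]

    Cfull = tree.node_vcv()
    tips = tree.tip_indices
    internals = [i for i in range(tree.n_nodes) if not tree.is_tip(i)]
    Ct = Cfull[np.ix_(tips, tips)]
    Cnt = Cfull[np.ix_(internals, tips)]
    mu = gls_mean(Y, Ct)
    resid = Y - mu
    est = mu + Cnt @ np.linalg.solve(Ct, resid)
    return {node: est[j] for j, node in enumerate(internals)}


class TransformedData(np.ndarray):
    """Array marker for phylogenetically transformed data.

    Exists so the API can refuse double application of the transform, which
    is statistically meaningless but easy to do by accident.
    """

    def __new__(cls, arr):
        return np.asarray(arr, float).view(cls)


def _inv_sqrt(C: np.ndarray, floor: float = 1e-12) -> np.ndarray:
    w, V = np.linalg.eigh(C)
    if w.min() < -1e-8 * max(w.max(), 1.0):
        raise ValueError("covariance matrix is not positive semi-definite")
    w = np.maximum(w, floor)
    return (V / np.sqrt(w)) @ V.T


def phylo_transform(data: np.ndarray, C: PhyloCovariance | np.ndarray) -> TransformedData:
    """Decorrelate species rows under BM: P^{-1/2} (data - 1 a') .

    ``a`` is the GLS phylogenetic mean and P^{-1/2} the inverse square root
    of the tip covariance (eigenvalues floored at 1e-12 against trees with
    near-zero terminal branches).  Applying the transform to already
    transformed data raises.
    """
    if isinstance(data, TransformedData):
        raise TypeError("data is already phylogenetically transformed; "
                        "the transform must not be applied twice")
    Cm = C.C if isinstance(C, PhyloCovariance) else np.asarray(C, float)
    X = np.asarray(data, float)
    if X.shape[0] != Cm.shape[0]:
        raise ValueError("data rows must match the covariance's tip order")
    mu = gls_mean(X, Cm)
    return TransformedData(_inv_sqrt(Cm) @ (X - mu))


def _kmult_stat(Y: np.ndarray, C: np.ndarray, Ci: np.ndarray,
                expected: float) -> float:
    one = np.ones(C.shape[0])
    w = Ci @ one
    mu = (w @ Y) / (one @ w)
    R = Y - mu
    num = float((R * R).sum())
    den = float(np.einsum("ip,ij,jp->", R, Ci, R))
    if den <= 0:
        raise ValueError("zero phylogenetically corrected variance")
    return (num / den) / expected


def kmult(data: np.ndarray, tree: Phylogeny, n_perm: int = 1000,
          rng: np.random.Generator | int | None = None,
          taxa: list[str] | None = None) -> SignalResult:
    """Multivariate phylogenetic signal (the Kmult generalisation of
    Blomberg's K).

    K is the ratio of the observed mean squared tip deviation from the
    phylogenetic mean (ordinary Euclidean) to its phylogenetically corrected
    counterpart, scaled by the BM expectation of that ratio, so K = 1 in
    expectation under single-rate BM.  The p-value permutes species' trait
    vectors across the tips and uses the (b+1)/(m+1) estimator.
    """
    rng = np.random.default_rng(rng)
    Y = np.atleast_2d(np.asarray(data, float))
    if Y.shape[0] == 1 and tree.n_tips > 1:
        Y = Y.T
    if tree.n_tips < 3:
        raise ValueError("need at least 3 species")
    order = taxa if taxa is not None else tree.tip_labels
    pos = {t: i for i, t in enumerate(order)}
    Y = Y[[pos[t] for t in tree.tip_labels]]
    if float(((Y - Y.mean(0)) ** 2).sum()) <= 0:
        raise ValueError("zero total variance in the data")

    C = tree.vcv()
    Ci = _inv(C)
    n = C.shape[0]
    one = np.ones(n)
    expected = (np.trace(C) - n / (one @ Ci @ one)) / (n - 1)
    obs = _kmult_stat(Y, C, Ci, expected)
    null = np.empty(n_perm)
    for b in range(n_perm):
        null[b] = _kmult_stat(Y[rng.permutation(n)], C, Ci, expected)
    return SignalResult(K=obs, p=perm_pvalue(null, obs, "ge"),
                        n_perm=n_perm, null=null)
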