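"""Ordination of species-mean shapes.

PCA of the flattened aligned coordinates (no phylogenetic correction, so
convergence remains visible), broken-stick axis selection, backtransforms
from score space to landmark configurations, and phylomorphospace
projection (tips plus BM ancestral estimates for internal nodes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gpa import AlignedShapes
from .phylo import ancestral_states_bm
from .tree import Phylogeny

__all__ = ["ShapeSpace", "pca_shapes", "broken_stick_axes",
           "broken_stick_expectation", "backtransform_shape",
           "Phylomorphospace", "phylomorphospace"]


@dataclass
class ShapeSpace:
    """PCA of species-mean shapes.

    ``scores`` are species x axes (zero column means), ``loadings`` are
    (k*d) x axes orthonormal, and ``proportion`` sums to 1 over the retained
    (non-degenerate) axes.
    """

    scores: np.ndarray
    eigenvalues: np.ndarray
    proportion: np.ndarray
    loadings: np.ndarray
    mean_shape: np.ndarray
    species: list[str]

    @property
    def n_axes(self) -> int:
        return self.scores.shape[1]

    @property
    def k(self) -> int:
        return self.mean_shape.shape[0]

    @property
    def d(self) -> int:
        return self.mean_shape.shape[1]


def pca_shapes(means: AlignedShapes) -> ShapeSpace:
    """Principal components of flattened species-mean shapes.

    SVD of the centered data matrix, covariance denominator n-1, axes
    truncated at the matrix rank.  Sign convention: the largest-magnitude
    loading of each axis is positive.
    """
    if means.n < 2:
        raise ValueError("PCA needs at least 2 species")
    X = means.flattened()
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eig = s ** 2 / (means.n - 1)
    keep = eig > max(eig.max(), 1.0) * 1e-12 if eig.max() > 0 else eig > -1
    U, s, Vt, eig = U[:, keep], s[keep], Vt[keep], eig[keep]
    # deterministic signs
    for a in range(Vt.shape[0]):
        j = int(np.argmax(np.abs(Vt[a])))
        if Vt[a, j] < 0:
            Vt[a] *= -1
            U[:, a] *= -1
    return ShapeSpace(
        scores=U * s,
        eigenvalues=eig,
        proportion=eig / eig.sum(),
        loadings=Vt.T,
        mean_shape=mean.reshape(means.k, means.d),
        species=list(means.species),
    )


def broken_stick_expectation(p: int) -> np.ndarray:
    """Expected ordered variance fractions of a unit stick broken into p parts:
    b_i = (1/p) * sum_{j=i..p} 1/j."""
    inv = 1.0 / np.arange(1, p + 1)
    return np.cumsum(inv[::-1])[::-1] / p


def broken_stick_axes(proportions: np.ndarray) -> int:
    """Number of leading axes whose variance share strictly exceeds the
    broken-stick expectation; stops at the first failure."""
    prop = np.asarray(proportions, float)
    if np.any(np.diff(prop) > 1e-12):
        raise ValueError("proportions must be sorted non-increasing")
    if not np.isclose(prop.sum(), 1.0, atol=1e-6):
        raise ValueError("proportions must sum to 1")
    b = broken_stick_expectation(prop.size)
    count = 0
    for pi, bi in zip(prop, b):
        if pi > bi:
            count += 1
        else:
            break
    return count


def backtransform_shape(space: ShapeSpace, axis_scores) -> np.ndarray:
    """Landmark configuration at a position in score space:
    mean shape + sum_a score_a * loading_a."""
    s = np.asarray(axis_scores, float).ravel()
    flat = space.mean_shape.ravel() + space.loadings[:, :s.size] @ s
    return flat.reshape(space.k, space.d)


@dataclass
class Phylomorphospace:
    """Tip and BM-ancestor positions in score space, with tree edges."""

    tip_scores: np.ndarray        # tips x axes, in tree tip order
    node_scores: dict[int, np.ndarray]
    edges: list[tuple[np.ndarray, np.ndarray]]
    taxa: list[str]
    axes: tuple[int, ...]


def phylomorphospace(space: ShapeSpace, tree: Phylogeny,
                     axes: tuple[int, ...] = (0, 1)) -> Phylomorphospace:
    """Project the phylogeny into the shape space.

    Internal nodes take their GLS Brownian-motion ancestral estimates,
    computed axis by axis; edges are (parent position, child position)
    pairs ready for plotting.
    """
    missing = set(tree.tip_labels) - set(space.species)
    if missing:
        raise ValueError(f"tree tips without scores: {sorted(missing)} "
                         "(prune the tree first)")
    axes = tuple(axes)
    pos = {s: i for i, s in enumerate(space.species)}
    Y = space.scores[[pos[t] for t in tree.tip_labels]][:, axes]
    anc = ancestral_states_bm(tree, Y)

    def node_pos(i: int) -> np.ndarray:
        if tree.is_tip(i):
            return Y[tree.tip_indices.index(i)]
        return anc[i]

    edges = [(node_pos(p), node_pos(c)) for p, c, _ in tree.edges()]
    return Phylomorphospace(tip_scores=Y, node_scores=anc, edges=edges,
                            taxa=tree.tip_labels, axes=axes)
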