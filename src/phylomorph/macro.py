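"""Convergence and disparity-through-time in shape space.

Convergence follows the C1-C4 family of metrics: how much of the maximum
past phenotypic distance between two lineages has been closed by the focal
tips (C1 as a fraction, C2 as a difference, C3/C4 scaled by the amount of
evolution along the lineages / in the spanning clade).  The ellipse-crossing
count places a minimal-area enclosing ellipse around the focal taxa in a 2-D
morphospace and counts root-to-tip lineages whose phylomorphospace polyline
enters it.  Disparity-through-time slices the time-calibrated tree at evenly
spaced times and takes the mean squared pairwise distance among the
interpolated lineage positions; a burst is a between-slice increase greater
than a fixed threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phylo import ancestral_states_bm, perm_pvalue, phylo_vcv
from .tree import Phylogeny

__all__ = ["ConvergenceResult", "convergence_c_metrics",
           "EllipseCrossing", "convnum_ellipse", "min_enclosing_ellipse",
           "DisparityProfile", "disparity_through_time", "detect_bursts"]


# ------------------------------------------------------------ C metrics

@dataclass
class ConvergenceResult:
    c1: float
    c2: float
    c3: float
    c4: float
    p: dict[str, float]
    n_sim: int
    focal_pair: tuple[str, str]
    dtip: float
    dmax: float


def _node_positions(tree: Phylogeny, scores: np.ndarray) -> dict[int, np.ndarray]:
    anc = ancestral_states_bm(tree, scores)
    pos = dict(anc)
    for j, t in enumerate(tree.tip_indices):
        pos[t] = scores[j]
    return pos


def _c_stats(tree: Phylogeny, scores: np.ndarray,
             focal_idx: list[int]) -> tuple[float, float, float, float, float, float, tuple[int, int]]:
    pos = _node_positions(tree, scores)
    tips = tree.tip_indices

    # Dtip: max pairwise distance among focal tips; that pair defines the lineages
    best, pair = -1.0, (focal_idx[0], focal_idx[1])
    for a in range(len(focal_idx)):
        for b in range(a + 1, len(focal_idx)):
            i, j = focal_idx[a], focal_idx[b]
            dd = float(np.linalg.norm(pos[i] - pos[j]))
            if dd > best:
                best, pair = dd, (i, j)
    dtip = best
    i, j = pair
    anc = tree.mrca(i, j)
    if anc in (i, j):
        raise ValueError("focal taxa lie on a single lineage (no divergence)")
    path_i = tree.ancestor_path(i)
    path_j = tree.ancestor_path(j)
    path_i = path_i[path_i.index(anc):]
    path_j = path_j[path_j.index(anc):]

    dmax = 0.0
    for a in path_i:
        for b in path_j:
            dmax = max(dmax, float(np.linalg.norm(pos[a] - pos[b])))
    c1 = 1.0 - dtip / dmax if dmax > 0 else 0.0
    c2 = dmax - dtip

    lineage_evo = 0.0
    for path in (path_i, path_j):
        for a, b in zip(path[:-1], path[1:]):
            lineage_evo += float(np.linalg.norm(pos[a] - pos[b]))
    c3 = c2 / lineage_evo if lineage_evo > 0 else 0.0

    clade_root = tree.mrca_of([tree.labels[t] for t in focal_idx])
    clade_evo = 0.0
    stack = [clade_root]
    while stack:
        u = stack.pop()
        for v in tree.children(u):
            clade_evo += float(np.linalg.norm(pos[u] - pos[v]))
            stack.append(v)
    c4 = c2 / clade_evo if clade_evo > 0 else 0.0
    return c1, c2, c3, c4, dtip, dmax, pair


def convergence_c_metrics(scores: np.ndarray, tree: Phylogeny,
                          focal_taxa: list[str], n_sim: int = 1000,
                          rng=None, taxa: list[str] | None = None) -> ConvergenceResult:
    """C1-C4 convergence metrics with BM-simulation p-values.

    ``scores`` are species x retained-axes positions in the order of
    ``taxa`` (default: the tree's tip order).  The null simulates multivariate
    BM on the tree with the evolutionary rate matrix estimated from the data
    and asks how often each metric is at least as large as observed, with the
    (b+1)/(n_sim+1) estimator.
    """
    if len(focal_taxa) < 2:
        raise ValueError("need at least 2 focal taxa")
    rng = np.random.default_rng(rng)
    Y = np.atleast_2d(np.asarray(scores, float))
    if Y.shape[0] == 1 and tree.n_tips > 1:
        Y = Y.T
    order = taxa if taxa is not None else tree.tip_labels
    pos = {t: i for i, t in enumerate(order)}
    Y = Y[[pos[t] for t in tree.tip_labels]]
    focal_idx = [tree.index_of(t) for t in focal_taxa]

    obs = _c_stats(tree, Y, focal_idx)
    c1, c2, c3, c4, dtip, dmax, pair = obs

    # evolutionary rate matrix from the data (GLS / BM estimator)
    C = tree.vcv()
    Ci = np.linalg.inv(C)
    one = np.ones(C.shape[0])
    mu = (one @ Ci @ Y) / (one @ Ci @ one)
    R = Y - mu
    Rmat = (R.T @ Ci @ R) / C.shape[0]
    Rmat = Rmat + 1e-12 * np.eye(Rmat.shape[0])
    Lc = np.linalg.cholesky(C + 1e-12 * np.eye(C.shape[0]))
    Lr = np.linalg.cholesky(Rmat)

    sims = np.empty((n_sim, 4))
    for s in range(n_sim):
        Ysim = Lc @ rng.standard_normal((C.shape[0], Y.shape[1])) @ Lr.T
        sims[s] = _c_stats(tree, Ysim, focal_idx)[:4]
    pvals = {name: perm_pvalue(sims[:, j], val, "ge")
             for j, (name, val) in enumerate(
                 zip(("c1", "c2", "c3", "c4"), (c1, c2, c3, c4)))}
    return ConvergenceResult(c1=c1, c2=c2, c3=c3, c4=c4, p=pvals, n_sim=n_sim,
                             focal_pair=(tree.labels[pair[0]], tree.labels[pair[1]]),
                             dtip=dtip, dmax=dmax)


# -------------------------------------------------- ellipse crossings

def min_enclosing_ellipse(points: np.ndarray, tol: float = 1e-8,
                          buffer: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Minimal-area enclosing ellipse (center c, matrix A with
    (x-c)'A(x-c) <= 1), by Khachiyan's algorithm.

    ``buffer`` inflates both semi-axes additively, which rescues degenerate
    (collinear) focal sets.
    """
    P = np.asarray(points, float)
    n, d = P.shape
    if n < d + 1:
        raise ValueError("need at least d+1 points in general position "
                         "(try a buffer radius)")
    Q = np.vstack([P.T, np.ones(n)])
    u = np.full(n, 1.0 / n)
    try:
        for _ in range(200000):
            X = Q @ np.diag(u) @ Q.T
            M = np.einsum("ij,jk,ki->i", Q.T, np.linalg.inv(X), Q)
            j = int(np.argmax(M))
            if M[j] <= (d + 1) * (1.0 + tol):
                break
            step = (M[j] - d - 1.0) / ((d + 1) * (M[j] - 1.0))
            u *= (1 - step)
            u[j] += step
        c = P.T @ u
        S = (P.T * u) @ P - np.outer(c, c)
        A = np.linalg.inv(S) / d
        # guarantee containment despite finite iteration count
        vals = np.einsum("ni,ij,nj->n", P - c, A, P - c)
        if vals.max() > 1.0:
            A = A / vals.max()
    except np.linalg.LinAlgError:
        raise ValueError("degenerate focal configuration; supply a buffer radius")
    w, V = np.linalg.eigh(A)
    if w.min() <= 0 or w.max() / w.min() > 1e12:
        if buffer <= 0:
            raise ValueError("degenerate focal configuration; supply a buffer radius")
    if buffer > 0:
        radii = 1.0 / np.sqrt(np.maximum(w, 1e-300)) + buffer
        A = (V / radii ** 2) @ V.T
    return c, A


def _segment_hits_ellipse(p: np.ndarray, q: np.ndarray, c: np.ndarray,
                          L: np.ndarray) -> bool:
    """Does segment pq intersect the ellipse interior ((x-c)'A(x-c) <= 1)?

    ``L`` maps ellipse space to the unit circle (A = L'L).
    """
    a = L @ (p - c)
    b = L @ (q - c)
    d = b - a
    dd = float(d @ d)
    if dd == 0:
        return float(a @ a) <= 1.0
    t = float(np.clip(-(a @ d) / dd, 0.0, 1.0))
    closest = a + t * d
    return float(closest @ closest) <= 1.0


@dataclass
class EllipseCrossing:
    count: int
    count_nonfocal: int
    area: float
    center: np.ndarray
    A: np.ndarray
    crossing_taxa: list[str]


def convnum_ellipse(scores: np.ndarray, tree: Phylogeny,
                    focal_taxa: list[str], taxa: list[str] | None = None,
                    buffer: float = 0.0) -> EllipseCrossing:
    """Count lineages entering the focal taxa's enclosing ellipse.

    ``scores`` must be a 2-D morphospace (two plotting axes).  Each
    root-to-tip lineage is the polyline through the BM ancestral positions;
    a lineage counts if any of its segments enters the ellipse interior.
    Counts both with and without the focal lineages themselves.
    """
    Y = np.asarray(scores, float)
    if Y.ndim != 2 or Y.shape[1] != 2:
        raise ValueError("exactly 2 plotting axes required")
    order = taxa if taxa is not None else tree.tip_labels
    pos_map = {t: i for i, t in enumerate(order)}
    Y = Y[[pos_map[t] for t in tree.tip_labels]]
    focal_idx = [tree.index_of(t) for t in focal_taxa]
    tipsY = {t: Y[j] for j, t in enumerate(tree.tip_indices)}
    c, A = min_enclosing_ellipse(np.array([tipsY[i] for i in focal_idx]),
                                 buffer=buffer)
    L = np.linalg.cholesky(A).T
    area = float(np.pi / np.sqrt(np.linalg.det(A)))

    pos = _node_positions(tree, Y)
    crossing, crossing_nonfocal = [], []
    focal_set = set(focal_idx)
    for t in tree.tip_indices:
        path = tree.ancestor_path(t)
        pts = [pos[i] for i in path]
        hit = any(_segment_hits_ellipse(p, q, c, L)
                  for p, q in zip(pts[:-1], pts[1:]))
        if len(pts) == 1:
            hit = _segment_hits_ellipse(pts[0], pts[0], c, L)
        if hit:
            crossing.append(tree.labels[t])
            if t not in focal_set:
                crossing_nonfocal.append(tree.labels[t])
    return EllipseCrossing(count=len(crossing),
                           count_nonfocal=len(crossing_nonfocal),
                           area=area, center=c, A=A, crossing_taxa=crossing)


# ------------------------------------------------- disparity through time

@dataclass
class DisparityProfile:
    times: np.ndarray
    disparity: np.ndarray
    clade: str
    bursts: list[tuple[int, int, float]] = field(default_factory=list)


def disparity_through_time(scores: np.ndarray, tree: Phylogeny,
                           n_slices: int = 31,
                           taxa: list[str] | None = None,
                           clades: dict[str, list[str]] | None = None,
                           clade_label: str = "all") -> dict[str, DisparityProfile]:
    """Morphological disparity at evenly spaced time slices.

    At each slice, every branch alive at that time contributes a point
    linearly interpolated between its parent's and child's (ancestral or
    tip) positions; disparity is the mean squared pairwise Euclidean
    distance among those points, so it is 0 at the root and equals the tip
    disparity at the present.  ``clades`` maps a label to a list of tip
    names; each named subclade (the subtree spanned by those tips) gets its
    own profile over its own depth.
    """
    if not tree.is_ultrametric():
        raise ValueError("disparity through time requires an ultrametric "
                         "(time-calibrated) tree")
    Y = np.atleast_2d(np.asarray(scores, float))
    if Y.shape[0] == 1 and tree.n_tips > 1:
        Y = Y.T
    order = taxa if taxa is not None else tree.tip_labels
    pos_map = {t: i for i, t in enumerate(order)}
    Y = Y[[pos_map[t] for t in tree.tip_labels]]

    out = {clade_label: _dtt_one(tree, Y, n_slices, clade_label)}
    for label, tips in (clades or {}).items():
        sub = tree.prune(tips)
        posn = {t: i for i, t in enumerate(tree.tip_labels)}
        Ysub = Y[[posn[t] for t in sub.tip_labels]]
        out[label] = _dtt_one(sub, Ysub, n_slices, label)
    return out


def _dtt_one(tree: Phylogeny, Y: np.ndarray, n_slices: int,
             label: str) -> DisparityProfile:
    pos = _node_positions(tree, Y)
    depth = tree.depths()
    T = tree.max_depth()
    times = np.linspace(0.0, T, n_slices)
    disp = np.zeros(n_slices)
    edges = tree.edges()
    for s, t in enumerate(times):
        pts = []
        for p, c, el in edges:
            d0, d1 = depth[p], depth[c]
            if d0 <= t <= d1:
                f = 0.0 if d1 == d0 else (t - d0) / (d1 - d0)
                pts.append(pos[p] + f * (pos[c] - pos[p]))
        if len(pts) < 2:
            disp[s] = 0.0
            continue
        P = np.asarray(pts)
        sq = ((P[:, None, :] - P[None, :, :]) ** 2).sum(-1)
        iu = np.triu_indices(len(pts), 1)
        disp[s] = float(sq[iu].mean())
    return DisparityProfile(times=times, disparity=disp, clade=label)


def detect_bursts(profile: DisparityProfile,
                  threshold: float = 10.0) -> list[tuple[int, int, float]]:
    """Intervals where disparity increases by strictly more than ``threshold``
    between consecutive slices.  Adjacent qualifying intervals are separate
    bursts."""
    deltas = np.diff(profile.disparity)
    bursts = [(i, i + 1, float(d)) for i, d in enumerate(deltas) if d > threshold]
    profile.bursts = bursts
    return bursts
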