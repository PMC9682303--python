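"""Generalized Procrustes analysis.

Translation is removed by centering, size by scaling every configuration to
unit centroid size (full Procrustes), and orientation by least-squares
rotation to an iteratively updated consensus.  Reflections are never allowed
in the optimal rotation (specimens have handedness), and the final consensus
is aligned to its principal axes so output orientation is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import LandmarkSet

__all__ = ["AlignedShapes", "gpa_align", "species_mean_shapes",
           "procrustes_distance", "optimal_rotation", "centroid_size"]


def centroid_size(config: np.ndarray) -> float:
    """Square root of summed squared landmark distances from the centroid."""
    c = config - config.mean(axis=0)
    return float(np.sqrt((c ** 2).sum()))


def optimal_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation R (det +1) minimising ||a @ R - b||_F for centered configs."""
    u, s, vt = np.linalg.svd(a.T @ b)
    r = u @ vt
    if np.linalg.det(r) < 0:
        u[:, -1] *= -1
        r = u @ vt
    return r


@dataclass
class AlignedShapes:
    """GPA-superimposed configurations.

    ``coords`` is specimens x k x d in dimensionless shape units (each
    configuration centered at the origin with unit centroid size);
    ``centroid_size`` keeps the pre-scaling sizes in the original units.
    """

    coords: np.ndarray
    centroid_size: np.ndarray
    consensus: np.ndarray
    specimen_ids: list[str]
    species: list[str]
    ss_history: list[float] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def k(self) -> int:
        return self.coords.shape[1]

    @property
    def d(self) -> int:
        return self.coords.shape[2]

    def flattened(self) -> np.ndarray:
        """n x (k*d) matrix; landmark i occupies columns i*d .. i*d+d-1."""
        return self.coords.reshape(self.n, self.k * self.d)

    def subset_species(self, order: Sequence[str],
                       normalized_from: Sequence[str] | None = None) -> "AlignedShapes":
        """Rows restricted and reordered to ``order`` (one row per species)."""
        labels = list(normalized_from) if normalized_from is not None else self.species
        pos = {s: i for i, s in enumerate(labels)}
        idx = [pos[s] for s in order]
        return AlignedShapes(
            coords=self.coords[idx].copy(),
            centroid_size=self.centroid_size[idx].copy(),
            consensus=self.consensus.copy(),
            specimen_ids=[self.specimen_ids[i] for i in idx],
            species=[self.species[i] for i in idx],
        )


def _center_scale(config: np.ndarray, name: str) -> tuple[np.ndarray, float]:
    c = config - config.mean(axis=0)
    cs = np.sqrt((c ** 2).sum())
    if cs < 1e-12:
        raise ValueError(f"specimen {name!r} has zero centroid size "
                         "(all landmarks coincident)")
    return c / cs, float(cs)


def gpa_align(shapes: Sequence[LandmarkSet], max_iter: int = 100,
              tol: float = 1e-10) -> AlignedShapes:
    """Superimpose landmark configurations by generalized Procrustes analysis.

    Iterates rotation-to-consensus / consensus-update until the consensus
    moves less than ``tol`` (summed squared change) or ``max_iter`` is hit.
    The total sum of squared deviations from the consensus is non-increasing
    across iterations.
    """
    if not shapes:
        raise ValueError("no configurations to align")
    k, d = shapes[0].k, shapes[0].d
    n = len(shapes)
    X = np.empty((n, k, d))
    sizes = np.empty(n)
    for i, s in enumerate(shapes):
        if (s.k, s.d) != (k, d):
            raise ValueError(f"specimen {s.specimen_id!r}: inconsistent dimensions")
        X[i], sizes[i] = _center_scale(s.coords, s.specimen_id)

    consensus = X[0].copy()
    ss_history: list[float] = []
    for _ in range(max_iter):
        for i in range(n):
            X[i] = X[i] @ optimal_rotation(X[i], consensus)
        ss_history.append(float(((X - consensus) ** 2).sum()))
        new = X.mean(axis=0)
        new -= new.mean(axis=0)
        new /= np.sqrt((new ** 2).sum())
        delta = float(((new - consensus) ** 2).sum())
        consensus = new
        if delta < tol:
            break

    # principal-axis alignment of the consensus for reproducible orientation
    _, _, vt = np.linalg.svd(consensus - consensus.mean(axis=0), full_matrices=False)
    rot = vt.T
    if np.linalg.det(rot) < 0:
        rot[:, -1] *= -1
    consensus = consensus @ rot
    X = X @ rot
    for i in range(n):  # final fit to the fixed consensus
        X[i] = X[i] @ optimal_rotation(X[i], consensus)

    return AlignedShapes(
        coords=X,
        centroid_size=sizes,
        consensus=consensus,
        specimen_ids=[s.specimen_id for s in shapes],
        species=[s.species for s in shapes],
        ss_history=ss_history,
    )


def species_mean_shapes(aligned: AlignedShapes) -> AlignedShapes:
    """Average aligned specimens within species (species sorted).

    Means of aligned configurations are re-centered but not re-superimposed:
    averages of unit-size centered shapes are already centered to within
    numerical error and sit negligibly below unit size for small variation.
    """
    species = sorted(set(aligned.species))
    k, d = aligned.k, aligned.d
    coords = np.empty((len(species), k, d))
    sizes = np.empty(len(species))
    labels = np.asarray(aligned.species)
    for i, sp in enumerate(species):
        idx = np.flatnonzero(labels == sp)
        m = aligned.coords[idx].mean(axis=0)
        coords[i] = m - m.mean(axis=0)
        sizes[i] = aligned.centroid_size[idx].mean()
    return AlignedShapes(
        coords=coords,
        centroid_size=sizes,
        consensus=aligned.consensus.copy(),
        specimen_ids=list(species),
        species=list(species),
    )


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Full Procrustes distance between two configurations.

    Root of the minimised sum of squared differences after centering,
    scaling to unit centroid size, and optimal (reflection-free) rotation.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("configurations must share k and d")
    ac, _ = _center_scale(a, "a")
    bc, _ = _center_scale(b, "b")
    r = optimal_rotation(ac, bc)
    return float(np.sqrt(((ac @ r - bc) ** 2).sum()))
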