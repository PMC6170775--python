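"""Geometric morphometrics: generalized Procrustes analysis, shape PCA
and broken-stick component retention.

Landmark configurations (here 30 points in 3-D per talus) are stripped
of position, scale and orientation by iterative Procrustes
superimposition, leaving Procrustes shape coordinates.  A PCA of the
vectorised shape coordinates ordinates the sample, and the broken-stick
null model decides how many components carry more variance than
expected by chance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "LandmarkSet",
    "AlignedShapes",
    "ShapePCA",
    "centroid_size",
    "gpa",
    "shape_pca",
    "project_shapes",
    "broken_stick",
    "broken_stick_proportions",
]


@dataclass
class LandmarkSet:
    """Raw k x 3 landmark coordinates for one specimen."""

    coords: np.ndarray
    specimen_id: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be k x 3")
        if not np.isfinite(self.coords).all():
            raise ValueError(f"specimen {self.specimen_id!r}: non-finite coordinate")

    @property
    def k(self) -> int:
        return int(self.coords.shape[0])


@dataclass
class AlignedShapes:
    """Procrustes-aligned configurations: n x k x 3 coordinates, the
    centroid size removed from each, and the consensus mean shape."""

    procrustes_coords: np.ndarray
    centroid_sizes: np.ndarray
    mean_shape: np.ndarray
    specimen_ids: list[str]
    n_iterations: int

    @property
    def n(self) -> int:
        return int(self.procrustes_coords.shape[0])

    @property
    def k(self) -> int:
        return int(self.procrustes_coords.shape[1])

    def flat(self) -> np.ndarray:
        """n x 3k vectorised coordinates."""
        return self.procrustes_coords.reshape(self.n, -1)


def centroid_size(coords: np.ndarray) -> float:
    """Square root of summed squared landmark distances from the centroid."""
    c = coords - coords.mean(axis=0)
    return float(np.sqrt((c**2).sum()))


def _optimal_rotation(x: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation (no reflection) minimising ||x R - target||."""
    u, _, vt = np.linalg.svd(x.T @ target)
    r = u @ vt
    if np.linalg.det(r) < 0:
        u[:, -1] *= -1.0
        r = u @ vt
    return r


def _principal_axes(mean: np.ndarray) -> np.ndarray:
    """Rotation (det +1) aligning the mean shape's principal axes with
    the coordinate axes, with a deterministic sign convention."""
    _, vecs = np.linalg.eigh(mean.T @ mean)
    r = vecs[:, ::-1]  # descending variance
    for j in range(3):
        k = np.argmax(np.abs(mean @ r[:, j]))
        if (mean @ r[:, j])[k] < 0:
            r[:, j] *= -1.0
    if np.linalg.det(r) < 0:
        r[:, 2] *= -1.0
    return r


def gpa(
    landmarks: list[LandmarkSet],
    tol: float = 1e-10,
    max_iter: int = 100,
) -> AlignedShapes:
    """Generalized Procrustes superimposition.

    Each configuration is centred and scaled to unit centroid size, then
    the set is iteratively rotated to the current mean shape (rotations
    only; reflections are not allowed) and the mean re-estimated, until
    the mean shape moves by less than ``tol`` or ``max_iter`` passes.
    """
    if len(landmarks) < 2:
        raise ValueError("GPA needs at least two configurations")
    k = landmarks[0].k
    if any(lm.k != k for lm in landmarks):
        bad = next(lm.specimen_id for lm in landmarks if lm.k != k)
        raise ValueError(f"specimen {bad!r}: landmark count differs from {k}")

    configs = []
    sizes = []
    for lm in landmarks:
        c = lm.coords - lm.coords.mean(axis=0)
        cs = np.sqrt((c**2).sum())
        if cs == 0:
            raise ValueError(f"specimen {lm.specimen_id!r}: degenerate configuration")
        configs.append(c / cs)
        sizes.append(cs)
    x = np.stack(configs)

    mean = x[0].copy()
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        for i in range(x.shape[0]):
            x[i] = x[i] @ _optimal_rotation(x[i], mean)
        new_mean = x.mean(axis=0)
        new_mean /= np.sqrt((new_mean**2).sum())
        if np.abs(new_mean - mean).max() < tol:
            mean = new_mean
            break
        mean = new_mean
    # final alignment onto the converged mean
    for i in range(x.shape[0]):
        x[i] = x[i] @ _optimal_rotation(x[i], mean)

    # standardize the global orientation (principal axes of the mean
    # shape) so the result does not depend on input order/orientation
    r = _principal_axes(x.mean(axis=0))
    x = x @ r
    mean = mean @ r

    return AlignedShapes(
        procrustes_coords=x,
        centroid_sizes=np.asarray(sizes),
        mean_shape=x.mean(axis=0),
        specimen_ids=[lm.specimen_id for lm in landmarks],
        n_iterations=n_iter,
    )


@dataclass
class ShapePCA:
    """Principal components of vectorised Procrustes coordinates."""

    scores: np.ndarray
    eigenvalues: np.ndarray
    loadings: np.ndarray  # p x 3k, rows are components
    mean: np.ndarray  # 3k
    retained: int

    @property
    def proportions(self) -> np.ndarray:
        return self.eigenvalues / self.eigenvalues.sum()


def shape_pca(aligned: AlignedShapes) -> ShapePCA:
    """PCA (covariance matrix) of the vectorised aligned coordinates.

    Scores reproduce the data exactly: data = mean + scores @ loadings.
    The retained count is filled in by ``broken_stick``.
    """
    if aligned.n < 3:
        raise ValueError("PCA needs at least three specimens")
    flat = aligned.flat()
    mean = flat.mean(axis=0)
    centred = flat - mean
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    eig = s**2 / (aligned.n - 1)
    scores = u * s
    pca = ShapePCA(scores=scores, eigenvalues=eig, loadings=vt, mean=mean, retained=0)
    pca.retained = broken_stick(eig)
    return pca


def project_shapes(pca: ShapePCA, aligned: AlignedShapes) -> np.ndarray:
    """Project (e.g. fossil) aligned shapes into an existing PC space."""
    return (aligned.flat() - pca.mean) @ pca.loadings.T


def broken_stick_proportions(p: int) -> np.ndarray:
    """Expected eigenvalue proportions b_k = (1/p) sum_{i=k..p} 1/i."""
    inv = 1.0 / np.arange(1, p + 1)
    return np.cumsum(inv[::-1])[::-1] / p


def broken_stick(eigenvalues: np.ndarray) -> int:
    """Number of leading components exceeding the broken-stick model.

    Only eigenvalues above 1e-12 of the largest count towards p; the
    retained count is the longest initial run with observed proportion
    strictly greater than the broken-stick expectation.
    """
    eig = np.asarray(eigenvalues, dtype=float)
    if eig.size == 0 or np.all(eig <= 0):
        raise ValueError("need at least one positive eigenvalue")
    if np.any(np.diff(eig) > 1e-9 * eig[0]):
        raise ValueError("eigenvalues must be in descending order")
    positive = eig > 1e-12 * eig[0]
    p = int(positive.sum())
    if p == 1:
        return 1
    props = eig[:p] / eig[:p].sum()
    expected = broken_stick_proportions(p)
    retained = 0
    for obs, exp in zip(props, expected):
        # strict inequality, robust to float rounding at exact equality
        if obs > exp + 1e-12 * max(exp, 1.0):
            retained += 1
        else:
            break
    if retained == 0:
        warnings.warn("no component exceeds the broken-stick expectation", stacklevel=2)
    return retained
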