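"""Generalized Procrustes analysis, centroid size, and Procrustes distances.

Partial Procrustes fitting: each configuration is translated to place its
centroid at the origin, scaled to unit centroid size, and iteratively rotated
(rotation only — reflections are never allowed, so left femora must be
mirrored beforehand) onto the evolving consensus until the consensus
stabilises. Centroid size, the usual geometric-morphometric size proxy, is
retained per specimen before scaling.

`GeneralizedProcrustes` is a scikit-learn style transformer over an
``n x k x 3`` landmark array; :func:`gpa_align` wraps it for
:class:`~femorph.landmarks.LandmarkConfiguration` lists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .landmarks import LandmarkConfiguration

log = logging.getLogger(__name__)


def centroid_size(config) -> float:
    """Square root of summed squared distances of landmarks to their centroid."""
    coords = config.coords if isinstance(config, LandmarkConfiguration) else np.asarray(config, float)
    if coords.shape[0] < 2:
        raise ValueError("centroid size needs at least 2 landmarks")
    centred = coords - coords.mean(axis=0)
    cs = float(np.sqrt((centred ** 2).sum()))
    if cs <= 0:
        raise ValueError("all landmarks coincide; centroid size undefined")
    return cs


def optimal_rotation(moving: np.ndarray, fixed: np.ndarray) -> np.ndarray:
    """Proper rotation R (det +1) minimizing ||moving @ R - fixed||_F.

    Closed-form orthogonal superimposition via SVD with the determinant
    constrained positive (Kabsch), so reflections can never sneak in.
    """
    H = moving.T @ fixed
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    return U @ D @ Vt


def _center_scale(coords: np.ndarray) -> tuple[np.ndarray, float]:
    centred = coords - coords.mean(axis=0)
    cs = float(np.sqrt((centred ** 2).sum()))
    if cs <= 0:
        raise ValueError("degenerate configuration (zero centroid size)")
    return centred / cs, cs


@dataclass
class AlignedSample:
    """GPA output: superimposed configurations, consensus, centroid sizes."""

    specimen_ids: list[str]
    aligned: np.ndarray          # n x k x 3, unit centroid size each
    consensus: np.ndarray        # k x 3
    centroid_sizes: np.ndarray   # n, pre-scaling (mm)
    iterations_used: int
    converged: bool
    scheme: object = None

    @property
    def n(self) -> int:
        return self.aligned.shape[0]

    @property
    def k(self) -> int:
        return self.aligned.shape[1]

    def residuals(self) -> np.ndarray:
        """n x 3k Procrustes residuals (aligned minus consensus, vectorized)."""
        return (self.aligned - self.consensus[None]).reshape(self.n, -1)

    def flattened(self) -> np.ndarray:
        """n x 3k vectorized aligned coordinates."""
        return self.aligned.reshape(self.n, -1)


class GeneralizedProcrustes(BaseEstimator, TransformerMixin):
    """Partial generalized Procrustes superimposition as a transformer.

    Parameters
    ----------
    scale : bool, default True
        Scale configurations to unit centroid size (partial Procrustes).
        ``False`` gives a size-preserving fit.
    tol : float, default 1e-10
        Convergence tolerance on the consensus root-mean-square change.
    max_iter : int, default 100

    Attributes
    ----------
    consensus_ : (k, 3) ndarray
        Mean shape of the aligned sample.
    aligned_ : (n, k, 3) ndarray
        The superimposed training configurations.
    centroid_sizes_ : (n,) ndarray
    n_iter_ : int
    converged_ : bool
    """

    def __init__(self, scale: bool = True, tol: float = 1e-10, max_iter: int = 100):
        self.scale = scale
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None):
        X = self._validate(X)
        n = X.shape[0]
        if n < 2:
            raise ValueError("GPA needs at least 2 configurations")
        shapes = np.empty_like(X)
        sizes = np.empty(n)
        for i in range(n):
            centred, cs = _center_scale(X[i])
            sizes[i] = cs
            shapes[i] = centred if self.scale else centred * cs

        consensus = shapes[0].copy()
        consensus = consensus / np.sqrt((consensus ** 2).sum()) if self.scale else consensus
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            for i in range(n):
                R = optimal_rotation(shapes[i], consensus)
                shapes[i] = shapes[i] @ R
            new_consensus = shapes.mean(axis=0)
            if self.scale:
                norm = np.sqrt((new_consensus ** 2).sum())
                if norm > 0:
                    new_consensus = new_consensus / norm
            delta = np.sqrt(((new_consensus - consensus) ** 2).mean())
            consensus = new_consensus
            if delta < self.tol:
                converged = True
                break
        if not converged:
            log.warning("GPA did not converge in %d iterations", self.max_iter)

        # final consensus as the plain mean of the aligned configurations
        self.consensus_ = shapes.mean(axis=0)
        self.aligned_ = shapes
        self.centroid_sizes_ = sizes
        self.n_iter_ = it
        self.converged_ = converged
        return self

    def transform(self, X):
        """Superimpose new configurations onto the fitted consensus."""
        X = self._validate(X)
        out = np.empty_like(X)
        for i in range(X.shape[0]):
            centred, cs = _center_scale(X[i])
            shape = centred if self.scale else centred * cs
            out[i] = shape @ optimal_rotation(shape, self.consensus_)
        return out

    @staticmethod
    def _validate(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[2] != 3:
            raise ValueError("expected an n x k x 3 landmark array")
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite coordinates")
        return X


def gpa_align(sample: list[LandmarkConfiguration], scale: bool = True,
              tol: float = 1e-10, max_iter: int = 100) -> AlignedSample:
    """Run GPA on a list of configurations sharing one scheme."""
    if len(sample) < 2:
        raise ValueError("GPA needs at least 2 configurations")
    schemes = {cfg.scheme.n_total for cfg in sample}
    if len(schemes) != 1:
        raise ValueError("configurations do not share a landmark scheme")
    X = np.stack([cfg.coords for cfg in sample])
    est = GeneralizedProcrustes(scale=scale, tol=tol, max_iter=max_iter).fit(X)
    return AlignedSample(
        specimen_ids=[cfg.specimen_id for cfg in sample],
        aligned=est.aligned_,
        consensus=est.consensus_,
        centroid_sizes=est.centroid_sizes_,
        iterations_used=est.n_iter_,
        converged=est.converged_,
        scheme=sample[0].scheme,
    )


def procrustes_distance(a: np.ndarray, b: np.ndarray, align: bool = True) -> float:
    """Root summed squared landmark-wise difference after superimposing b on a.

    With ``align=False`` the configurations are compared as given (useful for
    already-superimposed samples).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("configurations must have matching shapes")
    if align:
        a, _ = _center_scale(a)
        b, _ = _center_scale(b)
        b = b @ optimal_rotation(b, a)
    return float(np.sqrt(((a - b) ** 2).sum()))


def mean_shape(aligned: AlignedSample) -> np.ndarray:
    """Arithmetic mean of the aligned configurations (the consensus)."""
    return aligned.aligned.mean(axis=0)
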