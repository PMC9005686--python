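"""PCA of Procrustes residuals: morphospace, theoretical shapes, displacement fields.

The aligned sample is vectorized to ``n x 3k`` and decomposed about its mean
(covariance PCA on raw residual coordinates, the geometric-morphometrics
standard). Axis signs are fixed deterministically: an axis whose scores
correlate with log centroid size (|r| > 0.1) is oriented so that correlation
is positive (larger specimens score higher — "robusticity increases along the
axis"); otherwise the largest-magnitude loading is made positive.

Theoretical shapes are reconstructions ``mean + score * axis`` at chosen axis
positions (e.g. the observed extremes); displacement fields between two such
shapes drive the classic blue-to-red landmark-displacement visualisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from sklearn.base import BaseEstimator, TransformerMixin

from .procrustes import AlignedSample


class ShapePCA(BaseEstimator, TransformerMixin):
    """Principal component analysis of vectorized aligned shapes.

    Parameters
    ----------
    n_components : int or None
        Number of axes kept; None keeps all min(n-1, 3k) axes.

    Attributes
    ----------
    mean_ : (3k,) ndarray
    components_ : (m, 3k) ndarray, orthonormal rows in descending eigenvalue order
    explained_variance_ : (m,) ndarray (eigenvalues of the covariance)
    explained_variance_ratio_ : (m,) ndarray, sums to 1 over all retained axes
    scores_ : (n, m) ndarray, training scores
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, X, y=None, sizes: np.ndarray | None = None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 3:
            X = X.reshape(X.shape[0], -1)
        n = X.shape[0]
        if n < 3:
            raise ValueError("PCA needs at least 3 specimens")
        self.mean_ = X.mean(axis=0)
        centred = X - self.mean_
        # SVD of the centered data == eigendecomposition of the covariance
        U, s, Vt = np.linalg.svd(centred, full_matrices=False)
        eigvals = s ** 2 / (n - 1)
        m = min(n - 1, X.shape[1])
        if self.n_components is not None:
            m = min(m, self.n_components)
        axes = Vt[:m]
        scores = centred @ axes.T

        # deterministic sign convention
        if sizes is not None:
            log_cs = np.log(np.asarray(sizes, float))
        else:
            log_cs = None
        for j in range(m):
            flip = False
            if log_cs is not None and np.std(scores[:, j]) > 0 and np.std(log_cs) > 0:
                r = np.corrcoef(scores[:, j], log_cs)[0, 1]
                if abs(r) > 0.1:
                    flip = r < 0
                else:
                    flip = axes[j, np.argmax(np.abs(axes[j]))] < 0
            else:
                flip = axes[j, np.argmax(np.abs(axes[j]))] < 0
            if flip:
                axes[j] *= -1.0
                scores[:, j] *= -1.0

        total = eigvals.sum()
        self.components_ = axes
        self.explained_variance_ = eigvals[:m]
        self.explained_variance_ratio_ = (eigvals[:m] / total) if total > 0 else eigvals[:m]
        self.scores_ = scores
        self.n_samples_ = n
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 3:
            X = X.reshape(X.shape[0], -1)
        return (X - self.mean_) @ self.components_.T

    def inverse_transform(self, scores):
        scores = np.atleast_2d(np.asarray(scores, float))
        return self.mean_ + scores @ self.components_


@dataclass
class ShapeSpace:
    """Fitted morphospace: mean, orthonormal axes, scores, variance fractions."""

    specimen_ids: list[str]
    mean: np.ndarray                  # 3k
    axes: np.ndarray                  # m x 3k
    eigenvalues: np.ndarray           # m
    scores: np.ndarray                # n x m
    variance_fractions: np.ndarray    # m
    k: int

    def axis_scores(self, axis_index: int) -> np.ndarray:
        return self.scores[:, axis_index]


def fit_pca(aligned: AlignedSample, n_components: int | None = None) -> ShapeSpace:
    """PCA of an aligned sample's vectorized coordinates.

    The axis-sign convention uses the sample's (pre-scaling) centroid sizes so
    that size-correlated axes point toward larger specimens.
    """
    est = ShapePCA(n_components=n_components).fit(
        aligned.flattened(), sizes=aligned.centroid_sizes)
    return ShapeSpace(
        specimen_ids=list(aligned.specimen_ids),
        mean=est.mean_,
        axes=est.components_,
        eigenvalues=est.explained_variance_,
        scores=est.scores_,
        variance_fractions=est.explained_variance_ratio_,
        k=aligned.k,
    )


def theoretical_shape(space: ShapeSpace, axis_index: int, score: float) -> np.ndarray:
    """Configuration ``mean + score * axis`` reshaped to k x 3."""
    if not 0 <= axis_index < space.axes.shape[0]:
        raise IndexError(f"axis {axis_index} out of range")
    vec = space.mean + score * space.axes[axis_index]
    return vec.reshape(space.k, 3)


def axis_extreme_shapes(space: ShapeSpace, axis_index: int) -> tuple[np.ndarray, np.ndarray]:
    """Minimal and maximal theoretical shapes at the observed score extremes."""
    s = space.axis_scores(axis_index)
    return (theoretical_shape(space, axis_index, float(s.min())),
            theoretical_shape(space, axis_index, float(s.max())))


def identify_mode_axis(space: ShapeSpace, modes: dict[str, str],
                       n_axes: int = 5) -> int:
    """Index of the leading axis most associated with known locomotor modes.

    Mirrors the analyst's step of inspecting the morphospace and picking the
    axis along which bipedal and quadrupedal specimens separate: each of the
    first ``n_axes`` axes is scored by the absolute point-biserial correlation
    of its scores with the B/Q indicator over known-mode specimens, and the
    best axis index (0-based) is returned.
    """
    known = [(i, modes[sid]) for i, sid in enumerate(space.specimen_ids)
             if modes.get(sid) in ("B", "Q")]
    if len(known) < 3 or len({m for _, m in known}) < 2:
        raise ValueError("need known specimens of both modes")
    rows = np.array([i for i, _ in known])
    indicator = np.array([1.0 if m == "B" else 0.0 for _, m in known])
    best, best_r = 0, -1.0
    for ax in range(min(n_axes, space.scores.shape[1])):
        s = space.scores[rows, ax]
        if s.std() == 0:
            continue
        r = abs(np.corrcoef(s, indicator)[0, 1])
        if r > best_r:
            best, best_r = ax, r
    return best


def displacement_field(shape_a: np.ndarray, shape_b: np.ndarray) -> dict:
    """Per-landmark displacement vectors between two shapes plus a color ramp.

    Returns vectors ``b - a``, their magnitudes, and magnitudes min-max
    normalized to [0, 1] with an associated blue-to-red RGB ramp (cold = small
    displacement, hot = large).
    """
    a = np.asarray(shape_a, float)
    b = np.asarray(shape_b, float)
    if a.shape != b.shape:
        raise ValueError("shapes must share a scheme")
    vectors = b - a
    magnitudes = np.linalg.norm(vectors, axis=1)
    span = magnitudes.max() - magnitudes.min()
    if span > 0:
        normalized = (magnitudes - magnitudes.min()) / span
    else:
        normalized = np.zeros_like(magnitudes)
    colors = np.stack([
        np.round(255 * normalized),
        np.zeros_like(normalized),
        np.round(255 * (1.0 - normalized)),
    ], axis=1).astype(int)
    return {
        "vectors": vectors,
        "magnitudes": magnitudes,
        "normalized": normalized,
        "colors": colors,
    }


def morphospace_report(space: ShapeSpace, groups: dict[str, str],
                       axis_pair: tuple[int, int] = (0, 1)) -> dict:
    """Scores plus per-group 2D convex hulls on an axis pair.

    Parameters
    ----------
    groups:
        specimen_id -> group label.
    axis_pair:
        The two axis indices to report (default PC1/PC2).

    Degenerate groups (< 3 points, or collinear) are flagged and reported as
    the point list itself.
    """
    i, j = axis_pair
    pts = space.scores[:, [i, j]]
    table = [
        {"specimen_id": sid, f"PC{i+1}": float(p[0]), f"PC{j+1}": float(p[1]),
         "group": groups.get(sid)}
        for sid, p in zip(space.specimen_ids, pts)
    ]
    hulls = {}
    for label in sorted({g for g in groups.values()}):
        idx = [n for n, sid in enumerate(space.specimen_ids) if groups.get(sid) == label]
        gp = pts[idx]
        if len(gp) < 3:
            hulls[label] = {"degenerate": True, "vertices": gp.tolist(), "area": 0.0}
            continue
        try:
            hull = ConvexHull(gp)
        except QhullError:
            hulls[label] = {"degenerate": True, "vertices": gp.tolist(), "area": 0.0}
            continue
        hulls[label] = {
            "degenerate": False,
            "vertices": gp[hull.vertices].tolist(),
            "area": float(hull.volume),  # 2D: "volume" is the area
        }
    extremes = {
        f"PC{a+1}": {"min": float(space.scores[:, a].min()),
                     "max": float(space.scores[:, a].max())}
        for a in axis_pair
    }
    return {"scores": table, "hulls": hulls, "extremes": extremes,
            "variance_fractions": space.variance_fractions[list(axis_pair)].tolist()}
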