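"""Thin-plate-spline interpolation in 3D and its bending energy.

The map ``f(x) = c + B x + sum_i w_i U(|x - x_i|)`` with the 3D biharmonic
kernel ``U(r) = r`` interpolates a source configuration onto a target exactly.
The side conditions (kernel weights orthogonal to ``[1 | X]``) remove the
affine part from the kernel sum; the bending energy is the standard quadratic
form of the non-affine coefficients, zero precisely when the target is an
affine image of the source. Everything downstream — sliding semilandmarks,
mean-mesh warping, theoretical-shape visualisation — sits on this kernel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.linalg

_COND_LIMIT = 1e12


@dataclass
class TPSMap:
    """A fitted 3D thin-plate-spline interpolant."""

    source: np.ndarray          # k x 3
    affine_matrix: np.ndarray   # 3 x 3
    translation: np.ndarray     # 3
    weights: np.ndarray         # k x 3 non-affine coefficients
    bending_energy: float

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return apply_tps(self, points)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = json.dumps({
            "source": self.source.tolist(),
            "affine_matrix": self.affine_matrix.tolist(),
            "translation": self.translation.tolist(),
            "weights": self.weights.tolist(),
            "bending_energy": self.bending_energy,
        })
        if path is not None:
            Path(path).write_text(doc)
        return doc

    @classmethod
    def from_json(cls, doc: str | Path) -> "TPSMap":
        if isinstance(doc, Path) or (isinstance(doc, str) and not doc.lstrip().startswith("{")):
            doc = Path(doc).read_text()
        d = json.loads(doc)
        return cls(source=np.array(d["source"]),
                   affine_matrix=np.array(d["affine_matrix"]),
                   translation=np.array(d["translation"]),
                   weights=np.array(d["weights"]),
                   bending_energy=float(d["bending_energy"]))


def _kernel_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """U(r) = r between every row of `a` and every row of `b`."""
    diff = a[:, None, :] - b[None, :, :]
    return np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))


def fit_tps(source: np.ndarray, target: np.ndarray, ridge: float = 0.0) -> TPSMap:
    """Fit the exact 3D TPS interpolant mapping `source` onto `target`.

    Parameters
    ----------
    source, target:
        Matched k x 3 landmark configurations, k >= 5.
    ridge:
        Optional nonnegative smoothing added to the kernel diagonal
        (0 = exact interpolation, the default used throughout the pipeline).
    """
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    if source.shape != target.shape or source.ndim != 2 or source.shape[1] != 3:
        raise ValueError("source and target must be matching k x 3 arrays")
    k = source.shape[0]
    if k < 5:
        raise ValueError("TPS in 3D needs at least 5 landmarks")

    scale = max(float(np.ptp(source)), 1.0)
    d = _kernel_matrix(source, source)
    np.fill_diagonal(d, np.inf)
    coincident = np.argwhere(d < 1e-12 * scale)
    if len(coincident):
        pairs = sorted({tuple(sorted(int(i) for i in p)) for p in coincident})
        raise ValueError(f"coincident source landmarks at index pairs {pairs[:10]}")

    K = _kernel_matrix(source, source)
    if ridge:
        K = K + ridge * np.eye(k)
    P = np.hstack([np.ones((k, 1)), source])            # k x 4
    L = np.zeros((k + 4, k + 4))
    L[:k, :k] = K
    L[:k, k:] = P
    L[k:, :k] = P.T

    if np.linalg.cond(L) > _COND_LIMIT:
        raise ValueError("TPS system numerically singular "
                         "(degenerate source configuration)")

    rhs = np.zeros((k + 4, 3))
    rhs[:k] = target
    sol = scipy.linalg.solve(L, rhs)
    W = sol[:k]
    A = sol[k:]
    translation = A[0].copy()
    affine = A[1:].T.copy()                              # f(x) = c + affine @ x

    energy = bending_energy_of(W, K if not ridge else _kernel_matrix(source, source))
    return TPSMap(source=source.copy(), affine_matrix=affine,
                  translation=translation, weights=W, bending_energy=energy)


def bending_energy_of(weights: np.ndarray, kernel: np.ndarray) -> float:
    """Quadratic-form bending energy of non-affine coefficients.

    With the U(r)=r kernel and the side conditions holding, ``w^T K w`` is
    negative semidefinite per coordinate, so the (nonnegative) energy is its
    negation, summed over the three coordinates.
    """
    e = -float(np.einsum("id,ij,jd->", weights, kernel, weights))
    return max(e, 0.0)


def bending_energy(tps_map: TPSMap) -> float:
    """Bending energy of a fitted map (0 iff the map is affine)."""
    return tps_map.bending_energy


def apply_tps(tps_map: TPSMap, points: np.ndarray) -> np.ndarray:
    """Evaluate the fitted map row-wise on m x 3 `points`."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    U = _kernel_matrix(points, tps_map.source)
    return (tps_map.translation[None, :]
            + points @ tps_map.affine_matrix.T
            + U @ tps_map.weights)


def bending_energy_between(source: np.ndarray, target: np.ndarray) -> float:
    """Convenience: energy of the TPS deformation from `source` to `target`."""
    return fit_tps(source, target).bending_energy


def bending_energy_matrix(source: np.ndarray) -> np.ndarray:
    """The k x k bending-energy matrix of a source configuration.

    This is the upper-left block of the inverse bordered kernel system: for any
    target column y, the deformation's per-coordinate energy is ``y^T B y``.
    It is symmetric positive semidefinite and annihilates affine targets.
    Used by the sliding step, which minimizes exactly this form.
    """
    source = np.asarray(source, dtype=float)
    k = source.shape[0]
    K = _kernel_matrix(source, source)
    P = np.hstack([np.ones((k, 1)), source])
    L = np.zeros((k + 4, k + 4))
    L[:k, :k] = K
    L[:k, k:] = P
    L[k:, :k] = P.T
    Linv = scipy.linalg.inv(L)
    B = -Linv[:k, :k]
    return (B + B.T) / 2.0
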