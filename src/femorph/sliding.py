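"""Sliding semilandmarks: patch projection and bending-energy relaxation.

The registration protocol has three steps. (1) A TPS map fitted on the
anatomical and curve landmarks warps the template's surface semilandmarks
onto each specimen; each warped point is replaced by its nearest point on the
specimen mesh (*patch projection*). (2) Five iterations of spline relaxation
slide every specimen's semilandmarks against the complete template
configuration. (3) A partial-Procrustes consensus of all configurations is
computed and every specimen relaxed against it for two final iterations.

Each relaxation iteration solves the closed-form generalized-least-squares
step of the standard sliding protocol: semilandmarks move only along their
allowed directions (curve points along the local chain tangent, surface
points within the local tangent plane; anatomical landmarks are fixed) so as
to minimize the TPS bending energy of the reference-to-specimen deformation,
after which slid points are re-projected onto their geometry (curve points to
the digitized polyline, surface points to the mesh when one is available).
"""

from __future__ import annotations

import logging

import numpy as np

from .landmarks import LandmarkConfiguration, TriangleMesh
from .procrustes import centroid_size, gpa_align
from .tps import apply_tps, bending_energy_matrix, fit_tps

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def nearest_on_mesh(mesh: TriangleMesh, points: np.ndarray):
    """Exact nearest point on the mesh surface for each query point.

    Returns (projected points, distances, face normals at the hits).
    """
    from trimesh.proximity import closest_point_naive

    tm = mesh.to_trimesh()
    points = np.atleast_2d(np.asarray(points, float))
    closest, dist, tid = closest_point_naive(tm, points)
    normals = np.asarray(tm.face_normals)[tid]
    return np.asarray(closest, float), np.asarray(dist, float), normals


def project_to_polyline(points: np.ndarray, chain: np.ndarray) -> np.ndarray:
    """Project each point onto the closest segment of an open polyline."""
    points = np.atleast_2d(points)
    a = chain[:-1]
    b = chain[1:]
    ab = b - a                                            # s x 3
    denom = np.einsum("ij,ij->i", ab, ab)
    denom[denom == 0] = 1.0
    out = np.empty_like(points)
    for n, p in enumerate(points):
        t = np.clip(np.einsum("ij,ij->i", p - a, ab) / denom, 0.0, 1.0)
        cand = a + t[:, None] * ab
        d2 = ((cand - p) ** 2).sum(axis=1)
        out[n] = cand[np.argmin(d2)]
    return out


def chain_tangents(chain_coords: np.ndarray) -> np.ndarray:
    """Unit tangents along an ordered chain: central differences inside,
    one-sided at the endpoints."""
    t = np.empty_like(chain_coords)
    t[1:-1] = chain_coords[2:] - chain_coords[:-2]
    t[0] = chain_coords[1] - chain_coords[0]
    t[-1] = chain_coords[-1] - chain_coords[-2]
    norms = np.linalg.norm(t, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return t / norms


def _plane_basis(normals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two orthonormal in-plane vectors per unit normal."""
    n = normals / np.linalg.norm(normals, axis=1, keepdims=True)
    helper = np.tile(np.array([1.0, 0.0, 0.0]), (len(n), 1))
    parallel = np.abs(n[:, 0]) > 0.9
    helper[parallel] = np.array([0.0, 1.0, 0.0])
    u = np.cross(n, helper)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    v = np.cross(n, u)
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return u, v


def _surface_normals(config: LandmarkConfiguration,
                     mesh: TriangleMesh | None) -> np.ndarray:
    """Unit normals at the surface semilandmarks.

    From the nearest mesh face when a mesh is available; otherwise from a
    local plane fit over neighbouring surface semilandmarks (smallest
    principal direction of the 8 nearest patch points).
    """
    surf = config.scheme.surface_indices
    pts = config.coords[surf]
    if mesh is not None:
        _, _, normals = nearest_on_mesh(mesh, pts)
        return normals
    normals = np.empty_like(pts)
    nn = min(8, len(pts) - 1)
    for i, p in enumerate(pts):
        d2 = ((pts - p) ** 2).sum(axis=1)
        neigh = pts[np.argsort(d2)[: nn + 1]]
        centred = neigh - neigh.mean(axis=0)
        _, _, vt = np.linalg.svd(centred, full_matrices=False)
        normals[i] = vt[-1]
    return normals


# ---------------------------------------------------------------------------
# patch projection (step 1)
# ---------------------------------------------------------------------------

def project_surface_patch(
    template: LandmarkConfiguration,
    target_fixed: LandmarkConfiguration,
    target_mesh: TriangleMesh,
    max_distance_factor: float = 0.1,
) -> LandmarkConfiguration:
    """Transfer the template's surface patch onto a specimen.

    A TPS map is fitted from the template's anatomical+curve landmarks to the
    specimen's, used to warp the template surface semilandmarks toward the
    specimen, and each warped point is replaced by its nearest point on the
    specimen mesh. A warning counts points landing farther than
    ``max_distance_factor x`` the mesh bounding-box diagonal.
    """
    scheme = template.scheme
    fixed_idx = np.concatenate([scheme.anatomical_indices, scheme.curve_indices])
    surf_idx = scheme.surface_indices
    if len(surf_idx) == 0:
        raise ValueError("scheme has no surface semilandmarks to project")
    tps = fit_tps(template.coords[fixed_idx], target_fixed.coords[fixed_idx])
    warped = apply_tps(tps, template.coords[surf_idx])
    projected, dist, _ = nearest_on_mesh(target_mesh, warped)
    far = int((dist > max_distance_factor * target_mesh.bbox_diagonal).sum())
    if far:
        log.warning("project_surface_patch: %d/%d warped points farther than "
                    "%.0f%% of the mesh diagonal from the surface",
                    far, len(surf_idx), 100 * max_distance_factor)
    coords = target_fixed.coords.copy()
    coords[surf_idx] = projected
    return target_fixed.copy(coords=coords)


# ---------------------------------------------------------------------------
# relaxation (steps 2 and 3)
# ---------------------------------------------------------------------------

def _sliding_directions(config: LandmarkConfiguration,
                        mesh: TriangleMesh | None,
                        slide_curves: bool = True):
    """Stacked sliding directions: (owner landmark index, unit direction)."""
    scheme = config.scheme
    owners: list[int] = []
    dirs: list[np.ndarray] = []
    if slide_curves:
        for chain in scheme.curve_chains:
            tang = chain_tangents(config.coords[list(chain)])
            for i, t in zip(chain, tang):
                owners.append(i)
                dirs.append(t)
    surf = scheme.surface_indices
    if len(surf):
        normals = _surface_normals(config, mesh)
        u, v = _plane_basis(normals)
        for i, uu, vv in zip(surf, u, v):
            owners.append(i)
            dirs.append(uu)
            owners.append(i)
            dirs.append(vv)
    return np.array(owners, dtype=int), (np.stack(dirs) if dirs else np.empty((0, 3)))


def _gls_slide_step(coords: np.ndarray, B: np.ndarray,
                    owners: np.ndarray, dirs: np.ndarray,
                    clamp: float | None) -> np.ndarray:
    """One closed-form bending-energy-minimizing displacement.

    Minimizes  sum_d (x_d + U lam)^T B (x_d + U lam)  over the sliding
    amplitudes lam, where column (i, a) of U moves landmark ``owners[a]``
    along ``dirs[a]``. The normal equations use the Kronecker structure
    (B x Gram of directions) rather than forming the full 3k x 3k form.
    """
    if len(owners) == 0:
        return coords
    A = B[np.ix_(owners, owners)] * (dirs @ dirs.T)
    b = np.einsum("ij,ij->i", (B @ coords)[owners], dirs)
    lam = -np.linalg.lstsq(A, b, rcond=None)[0]
    disp = np.zeros_like(coords)
    np.add.at(disp, owners, lam[:, None] * dirs)
    if clamp is not None:
        norms = np.linalg.norm(disp, axis=1)
        over = norms > clamp
        if np.any(over):
            disp[over] *= (clamp / norms[over])[:, None]
    out = coords + disp
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("sliding step produced non-finite coordinates")
    return out


def relax_to_reference(
    config: LandmarkConfiguration,
    reference: np.ndarray | LandmarkConfiguration,
    mesh: TriangleMesh | None = None,
    n_iter: int = 5,
    clamp_fraction: float = 0.1,
    slide_curves: bool = True,
) -> LandmarkConfiguration:
    """Slide a specimen's semilandmarks to minimize bending energy to a reference.

    Per iteration: estimate tangent directions at the current positions, take
    the closed-form GLS sliding step (anatomical landmarks never move), then
    re-project slid curve points onto their digitized polylines and surface
    points onto the mesh (skipped, with a log notice, when no mesh is given).
    ``n_iter=0`` returns the input unchanged.
    """
    ref = reference.coords if isinstance(reference, LandmarkConfiguration) else np.asarray(reference, float)
    scheme = config.scheme
    if ref.shape != config.coords.shape:
        raise ValueError("config and reference must share the landmark scheme")
    if n_iter == 0:
        return config.copy()
    B = bending_energy_matrix(ref)
    coords = config.coords.copy()
    anat = scheme.anatomical_indices
    clamp = clamp_fraction * centroid_size(coords) if clamp_fraction else None
    chains = [np.array(c, dtype=int) for c in scheme.curve_chains]
    polylines = [coords[c].copy() for c in chains]        # digitized geometry
    if mesh is None and len(scheme.surface_indices):
        log.info("relax_to_reference: no mesh; surface re-projection skipped")
    work = config.copy(coords=coords)
    for _ in range(int(n_iter)):
        owners, dirs = _sliding_directions(work, mesh, slide_curves=slide_curves)
        new = _gls_slide_step(work.coords, B, owners, dirs, clamp)
        new[anat] = config.coords[anat]                   # anatomical: bitwise fixed
        if slide_curves:
            for c, poly in zip(chains, polylines):
                new[c] = project_to_polyline(new[c], poly)
        surf = scheme.surface_indices
        if mesh is not None and len(surf):
            new[surf], _, _ = nearest_on_mesh(mesh, new[surf])
        work = work.copy(coords=new)
    return work


def slide_sample_to_consensus(
    sample: list[LandmarkConfiguration],
    meshes: list[TriangleMesh | None] | None = None,
    n_iter: int = 2,
    clamp_fraction: float = 0.1,
    slide_curves: bool = True,
) -> list[LandmarkConfiguration]:
    """Final relaxation of every specimen against the evolving Procrustes consensus.

    Per iteration the partial-Procrustes consensus is recomputed from the
    current configurations, then each specimen is relaxed one step against it
    (bending energy is affine-invariant, so the unit-size consensus is a valid
    reference for raw-size specimens). Default two iterations.
    """
    if meshes is None:
        meshes = [None] * len(sample)
    configs = [c.copy() for c in sample]
    for _ in range(int(n_iter)):
        aligned = gpa_align(configs)
        ref = aligned.consensus
        energy = [fit_tps(ref, a).bending_energy for a in aligned.aligned]
        log.info("slide_sample_to_consensus: mean bending energy %.6g", float(np.mean(energy)))
        configs = [
            relax_to_reference(cfg, _rescale_reference(ref, cfg), mesh=m, n_iter=1,
                               clamp_fraction=clamp_fraction, slide_curves=slide_curves)
            for cfg, m in zip(configs, meshes)
        ]
    return configs


def _rescale_reference(ref: np.ndarray, config: LandmarkConfiguration) -> np.ndarray:
    """Scale/position the unit-size consensus near the specimen (conditioning only;
    the bending-energy criterion itself is affine-invariant)."""
    cs = centroid_size(config.coords)
    return ref * cs + config.coords.mean(axis=0)


def strip_delimitation_curves(config: LandmarkConfiguration) -> LandmarkConfiguration:
    """Drop delimitation semilandmarks after sliding, before shape statistics."""
    scheme = config.scheme
    delim = scheme.delimitation_indices
    if len(delim) == 0:
        return config.copy()
    keep = np.array([i for i in range(scheme.n_total) if scheme.roles[i] != "delimitation"])
    return LandmarkConfiguration(
        specimen_id=config.specimen_id,
        coords=config.coords[keep],
        scheme=scheme.without_delimitation(),
        side=config.side,
        mirrored=config.mirrored,
    )
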