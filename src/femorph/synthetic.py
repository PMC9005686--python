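"""Synthetic femora with the statistical structure the analysis assumes.

Tip shapes are built in vectorized shape space as

    y_i = template
        + beta * (log CS_i - mean log CS) * v_size      (allometry)
        + delta * 1[mode_i = B] * v_mode                (locomotor offset)
        + sum_j z_ij * v_extra_j,  z_.j ~ MVN(0, sigma_phy^2 C)   (Brownian motion)
        + N(0, sigma_e^2) on every coordinate           (tip noise)

with orthonormal mode vectors constructed orthogonal to the template's
similarity directions (translation, rotation, scale), so each effect is a
pure shape deformation that survives Procrustes superimposition. Each shape
is then scaled to its centroid size (log sizes uniform on [log 40, log 800]
mm, the span of the study sample's femoral lengths) and randomly rotated and
translated; GPA has to undo exactly what the generator applied.

What this emulates: one dominant allometric axis, one group-separating axis,
Brownian phylogenetic covariance on the remaining modes, and digitization
noise. What it does not emulate: realistic femoral geometry, taphonomic
distortion, correlated (non-isotropic) digitization error, or unequal group
sizes — passing recovery tests shows the estimators work under the model's
assumptions, not that real bones satisfy them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .landmarks import (LandmarkConfiguration, LandmarkScheme, SpecimenRecord,
                        TriangleMesh, small_scheme)
from .phylo import Phylogeny, bm_covariance
from .procrustes import centroid_size

LOG_SIZE_RANGE = (np.log(40.0), np.log(800.0))


# ---------------------------------------------------------------------------
# template geometry
# ---------------------------------------------------------------------------

def make_template(scheme: LandmarkScheme | None = None) -> np.ndarray:
    """Deterministic bent-tube template for a scheme: two ellipsoidal ends and
    a curved shaft, centered, unit centroid size."""
    scheme = scheme or small_scheme()
    k = scheme.n_total
    coords = np.zeros((k, 3))
    golden = np.pi * (3.0 - np.sqrt(5.0))

    def tube_point(z: float, theta: float) -> np.ndarray:
        # radius swells at both ends; the shaft bows in +x
        r = 0.18 + 0.14 * np.exp(-((z - 0.0) / 0.18) ** 2) \
                 + 0.17 * np.exp(-((z - 1.0) / 0.18) ** 2)
        bend = 0.25 * np.sin(np.pi * z)
        return np.array([r * np.cos(theta) + bend, r * np.sin(theta), z])

    anat = scheme.anatomical_indices
    for j, i in enumerate(anat):
        z = 0.02 if j % 2 == 0 else 0.98
        coords[i] = tube_point(z, golden * j)

    delim = set(scheme.delimitation_indices.tolist())
    for c, chain in enumerate(scheme.curve_chains):
        if delim and chain[0] in delim:
            # delimitation ring: a full circle at the shaft boundary
            z = 0.25 if c % 2 == 0 else 0.75
            for j, i in enumerate(chain):
                coords[i] = tube_point(z, 2 * np.pi * j / len(chain))
        else:
            # longitudinal curve at a fixed angle
            theta = golden * (c + 1)
            for j, i in enumerate(chain):
                z = 0.05 + 0.9 * j / max(len(chain) - 1, 1)
                coords[i] = tube_point(z, theta)

    surf = scheme.surface_indices
    for j, i in enumerate(surf):
        # surface patches concentrated on the two epiphyses
        frac = j / max(len(surf) - 1, 1)
        z = 0.22 * frac / 0.5 if frac < 0.5 else 1.0 - 0.22 * (1 - frac) / 0.5
        coords[i] = tube_point(z, golden * j * 2.0)

    coords -= coords.mean(axis=0)
    coords /= centroid_size(coords)
    return coords


def _similarity_basis(template: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the similarity directions at the template:
    3 translations, 3 infinitesimal rotations, 1 scaling (7 x 3k)."""
    k = template.shape[0]
    basis = []
    for d in range(3):
        v = np.zeros((k, 3))
        v[:, d] = 1.0
        basis.append(v.ravel())
    gens = [
        np.array([[0, -1, 0], [1, 0, 0], [0, 0, 0]], float),
        np.array([[0, 0, 1], [0, 0, 0], [-1, 0, 0]], float),
        np.array([[0, 0, 0], [0, 0, -1], [0, 1, 0]], float),
    ]
    for G in gens:
        basis.append((template @ G.T).ravel())
    basis.append(template.ravel())
    B = np.stack(basis)
    Q, _ = np.linalg.qr(B.T)
    return Q.T  # 7 x 3k, orthonormal


def make_mode_vectors(template: np.ndarray, n_modes: int,
                      seed: int | None = None) -> np.ndarray:
    """Random orthonormal shape modes orthogonal to the similarity directions."""
    rng = np.random.default_rng(seed)
    dim = template.size
    sim = _similarity_basis(template)
    raw = rng.standard_normal((dim, n_modes))
    raw -= sim.T @ (sim @ raw)
    Q, _ = np.linalg.qr(raw)
    return Q.T  # n_modes x 3k


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def simulate_tree(n_tips: int, seed: int | None = None) -> Phylogeny:
    """Random rooted binary topology by uniform edge attachment, unit lengths."""
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(n_tips)])
    tree = dendropy.Tree(taxon_namespace=taxa)
    left = dendropy.Node(taxon=taxa[0])
    right = dendropy.Node(taxon=taxa[1])
    tree.seed_node.add_child(left)
    tree.seed_node.add_child(right)
    attachable = [left, right]
    for i in range(2, n_tips):
        target = attachable[int(rng.integers(len(attachable)))]
        parent = target.parent_node
        new_internal = dendropy.Node()
        parent.remove_child(target)
        parent.add_child(new_internal)
        new_internal.add_child(target)
        tip = dendropy.Node(taxon=taxa[i])
        new_internal.add_child(tip)
        attachable.append(new_internal)
        attachable.append(tip)
    phy = Phylogeny(tree=tree)
    phy.set_unit_lengths()
    return phy


# ---------------------------------------------------------------------------
# samples
# ---------------------------------------------------------------------------

@dataclass
class SyntheticTruth:
    """Ground truth of a simulated sample."""

    template: np.ndarray
    v_size: np.ndarray
    v_mode: np.ndarray
    v_extras: np.ndarray           # n_extras x 3k
    beta: float
    delta: float
    sigma_phy: float
    sigma_e: float
    sigma_d: float
    tree: Phylogeny
    modes: dict[str, str]          # tip -> B/Q
    log_sizes: dict[str, float]
    seed: int | None
    scheme: LandmarkScheme = field(default_factory=small_scheme)


def default_truth(
    n_tips: int = 36,
    scheme: LandmarkScheme | None = None,
    beta: float = 0.05,
    delta: float = 0.06,
    sigma_phy: float = 0.008,
    sigma_e: float = 0.003,
    sigma_d: float = 0.002,
    n_extras: int = 3,
    seed: int | None = None,
    tree: Phylogeny | None = None,
) -> SyntheticTruth:
    """Study-condition defaults: 36 taxa, log sizes spanning 40-800 mm, an
    allometric axis stronger than the group axis, mild Brownian covariance,
    and small digitization noise."""
    rng = np.random.default_rng(seed)
    scheme = scheme or small_scheme()
    template = make_template(scheme)
    modes_mat = make_mode_vectors(template, 2 + n_extras,
                                  seed=int(rng.integers(2 ** 31)))
    tree = tree or simulate_tree(n_tips, seed=int(rng.integers(2 ** 31)))
    tips = tree.tip_labels
    group = {t: ("B" if rng.random() < 0.5 else "Q") for t in tips}
    # guarantee both classes exist
    if len(set(group.values())) == 1:
        group[tips[0]] = "B" if group[tips[0]] == "Q" else "Q"
    log_sizes = {t: float(rng.uniform(*LOG_SIZE_RANGE)) for t in tips}
    return SyntheticTruth(
        template=template,
        v_size=modes_mat[0], v_mode=modes_mat[1], v_extras=modes_mat[2:],
        beta=beta, delta=delta, sigma_phy=sigma_phy, sigma_e=sigma_e,
        sigma_d=sigma_d, tree=tree, modes=group, log_sizes=log_sizes, seed=seed,
        scheme=scheme,
    )


def simulate_sample(truth: SyntheticTruth, seed: int | None = None
                    ) -> tuple[list[LandmarkConfiguration], list[SpecimenRecord]]:
    """Draw one landmark sample (plus metadata) from a ground truth.

    Shapes compose the allometric, group, Brownian and noise effects in mode
    space, then each configuration is scaled to its centroid size and given a
    random rotation and translation.
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    tips = truth.tree.tip_labels
    n = len(tips)
    k = truth.scheme.n_total
    base = truth.template.ravel()
    logs = np.array([truth.log_sizes[t] for t in tips])
    logc = logs - logs.mean()

    bm = np.zeros((n, len(truth.v_extras)))
    if truth.sigma_phy > 0 and len(truth.v_extras):
        C, _ = bm_covariance(truth.tree, order=tips)
        L = np.linalg.cholesky(C + 1e-12 * np.eye(n))
        bm = truth.sigma_phy * (L @ rng.standard_normal((n, len(truth.v_extras))))

    configs = []
    records = []
    for i, tip in enumerate(tips):
        y = base + truth.beta * logc[i] * truth.v_size
        if truth.modes[tip] == "B":
            y = y + truth.delta * truth.v_mode
        for j in range(len(truth.v_extras)):
            y = y + bm[i, j] * truth.v_extras[j]
        y = y + truth.sigma_e * rng.standard_normal(y.size)
        coords = y.reshape(k, 3)
        coords = coords - coords.mean(axis=0)
        cs = np.exp(logs[i])
        coords = coords * (cs / centroid_size(coords))
        coords = coords @ _random_rotation(rng).T + rng.normal(scale=cs, size=3)
        configs.append(LandmarkConfiguration(specimen_id=tip, coords=coords,
                                             scheme=truth.scheme))
        records.append(SpecimenRecord(
            specimen_id=tip, species=tip,
            clade="avemetatarsalian" if truth.modes[tip] == "B" else "pseudosuchian",
            input_mode=truth.modes[tip], femoral_length=cs,
        ))
    return configs, records


def _random_rotation(rng) -> np.ndarray:
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    return Q


def replicate_digitization(config: LandmarkConfiguration, sigma_d: float,
                           n_replicates: int = 10,
                           seed: int | None = None) -> list[LandmarkConfiguration]:
    """Replicated digitizations of one specimen with iid coordinate noise.

    Emulates the repeatability protocol: the same bone landmarked
    ``n_replicates`` times (default 10), differing only by operator error of
    scale ``sigma_d`` (mm)."""
    if sigma_d < 0:
        raise ValueError("sigma_d must be nonnegative")
    rng = np.random.default_rng(seed)
    out = []
    for r in range(n_replicates):
        noise = rng.normal(scale=sigma_d, size=config.coords.shape) if sigma_d else 0.0
        out.append(config.copy(specimen_id=f"{config.specimen_id}_rep{r}",
                               coords=config.coords + noise))
    return out


# ---------------------------------------------------------------------------
# meshes
# ---------------------------------------------------------------------------

def make_test_mesh(kind: str, params: dict | None = None,
                   resolution: int = 3,
                   with_landmarks: int = 0,
                   seed: int | None = None):
    """Watertight parametric mesh with known geometry.

    kind:
        ``cylinder`` (radius, length), ``sphere`` (radius),
        ``ellipsoid`` (radii: 3-tuple).
    with_landmarks:
        If positive, also return that many points spread evenly over the
        surface (golden-spiral on spheres/ellipsoids, helix on cylinders).
    """
    import trimesh

    params = params or {}
    if kind == "cylinder":
        r = float(params.get("radius", 10.0))
        length = float(params.get("length", 100.0))
        mesh = trimesh.creation.cylinder(radius=r, height=length,
                                         sections=max(32, 16 * resolution))
        pts = None
        if with_landmarks:
            t = np.linspace(0, 1, with_landmarks)
            theta = 2 * np.pi * 3.5 * t
            pts = np.stack([r * np.cos(theta), r * np.sin(theta),
                            length * (t - 0.5)], axis=1)
    elif kind in ("sphere", "ellipsoid"):
        radii = (np.array([params.get("radius", 1.0)] * 3, float)
                 if kind == "sphere"
                 else np.asarray(params.get("radii", (3.0, 2.0, 1.0)), float))
        mesh = trimesh.creation.icosphere(subdivisions=resolution)
        mesh.apply_scale(radii)
        pts = None
        if with_landmarks:
            i = np.arange(with_landmarks)
            phi = np.arccos(1 - 2 * (i + 0.5) / with_landmarks)
            theta = np.pi * (1 + 5 ** 0.5) * i
            unit = np.stack([np.sin(phi) * np.cos(theta),
                             np.sin(phi) * np.sin(theta),
                             np.cos(phi)], axis=1)
            pts = unit * radii
    else:
        raise ValueError(f"unknown mesh kind {kind!r}")
    tmesh = TriangleMesh(vertices=np.asarray(mesh.vertices, float),
                         faces=np.asarray(mesh.faces, int))
    return (tmesh, pts) if with_landmarks else tmesh
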