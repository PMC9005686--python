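"""Core in-memory types: landmark schemes, configurations, meshes, metadata.

A *landmark scheme* fixes, once per study, how many points are digitized on
every bone and what role each point plays:

* ``anatomical`` — discrete homologous points, never moved after digitization;
* ``curve`` — sliding semilandmarks strung along ordered curves (polylines);
* ``surface`` — sliding semilandmarks spread over surface patches;
* ``delimitation`` — curve semilandmarks that only bound the surface patches
  and are stripped before any shape statistics.

The packaged femoral scheme has 20 anatomical, 176 curve and 229 surface
landmarks (425 total), matching the published digitization protocol for
archosauriform femora; the two shaft delimitation rings are a flagged subset
of the curve landmarks.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

ROLES = ("anatomical", "curve", "surface", "delimitation")


@dataclass(frozen=True)
class LandmarkScheme:
    """Immutable description of a landmark template.

    Parameters
    ----------
    n_total:
        Number of landmarks per configuration.
    roles:
        Tuple of length ``n_total`` with one of :data:`ROLES` per landmark.
    curve_chains:
        Ordered index tuples, each an individual digitized curve (polyline) of
        curve or delimitation semilandmarks. Chains must have >= 3 points.
    patch_indices:
        Indices of the surface semilandmarks.
    name:
        Free-text identifier.
    """

    n_total: int
    roles: tuple[str, ...]
    curve_chains: tuple[tuple[int, ...], ...] = ()
    patch_indices: tuple[int, ...] = ()
    name: str = "unnamed"

    def __post_init__(self) -> None:
        if len(self.roles) != self.n_total:
            raise ValueError(
                f"scheme declares {self.n_total} landmarks but {len(self.roles)} roles"
            )
        bad = sorted({r for r in self.roles} - set(ROLES))
        if bad:
            raise ValueError(f"unknown landmark roles: {bad}")
        for chain in self.curve_chains:
            if len(chain) < 3:
                raise ValueError("every curve chain needs >= 3 semilandmarks")
            for i in chain:
                if self.roles[i] not in ("curve", "delimitation"):
                    raise ValueError(
                        f"chain index {i} has role {self.roles[i]!r}, expected curve/delimitation"
                    )
        for i in self.patch_indices:
            if self.roles[i] != "surface":
                raise ValueError(f"patch index {i} has role {self.roles[i]!r}")

    # -- derived index sets ------------------------------------------------
    def indices_with_role(self, *roles: str) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.roles) if r in roles], dtype=int)

    @property
    def anatomical_indices(self) -> np.ndarray:
        return self.indices_with_role("anatomical")

    @property
    def curve_indices(self) -> np.ndarray:
        """Curve semilandmarks *including* the delimitation subset."""
        return self.indices_with_role("curve", "delimitation")

    @property
    def surface_indices(self) -> np.ndarray:
        return self.indices_with_role("surface")

    @property
    def delimitation_indices(self) -> np.ndarray:
        return self.indices_with_role("delimitation")

    def role_counts(self) -> dict[str, int]:
        counts = {r: 0 for r in ROLES}
        for r in self.roles:
            counts[r] += 1
        return counts

    def without_delimitation(self) -> "LandmarkScheme":
        """Scheme with the delimitation semilandmarks removed and indices remapped."""
        keep = [i for i, r in enumerate(self.roles) if r != "delimitation"]
        remap = {old: new for new, old in enumerate(keep)}
        chains = []
        for chain in self.curve_chains:
            kept = tuple(remap[i] for i in chain if i in remap)
            if len(kept) >= 3:
                chains.append(kept)
        return LandmarkScheme(
            n_total=len(keep),
            roles=tuple(self.roles[i] for i in keep),
            curve_chains=tuple(chains),
            patch_indices=tuple(remap[i] for i in self.patch_indices),
            name=self.name + "-nodelim",
        )


def make_scheme(
    n_anatomical: int,
    n_curve: int,
    n_surface: int,
    n_delimitation: int = 0,
    points_per_chain: int = 8,
    name: str = "generic",
) -> LandmarkScheme:
    """Build a scheme with the standard index layout.

    Landmarks are laid out as ``anatomical | curve | delimitation | surface``.
    ``n_delimitation`` counts toward the curve total (delimitation rings are
    digitized as curves), so ``n_curve`` must include it. Curve landmarks are
    grouped into chains of ``points_per_chain`` consecutive indices (the final
    chain absorbs the remainder); each delimitation ring is one chain.
    """
    if n_delimitation and n_delimitation >= n_curve:
        raise ValueError("delimitation count must be a strict subset of the curve count")
    n_plain_curve = n_curve - n_delimitation
    roles = (
        ["anatomical"] * n_anatomical
        + ["curve"] * n_plain_curve
        + ["delimitation"] * n_delimitation
        + ["surface"] * n_surface
    )
    chains: list[tuple[int, ...]] = []
    start = n_anatomical
    idx = list(range(start, start + n_plain_curve))
    while idx:
        take = idx[: points_per_chain * 2] if len(idx) < points_per_chain * 2 else idx[:points_per_chain]
        if len(idx) - len(take) in (1, 2):  # avoid stub chains < 3 points
            take = idx
        chains.append(tuple(take))
        idx = idx[len(take):]
    if n_delimitation:
        half = n_delimitation // 2
        d0 = start + n_plain_curve
        ring1 = tuple(range(d0, d0 + half))
        ring2 = tuple(range(d0 + half, d0 + n_delimitation))
        for ring in (ring1, ring2):
            if len(ring) >= 3:
                chains.append(ring)
    surf0 = n_anatomical + n_curve
    return LandmarkScheme(
        n_total=n_anatomical + n_curve + n_surface,
        roles=tuple(roles),
        curve_chains=tuple(chains),
        patch_indices=tuple(range(surf0, surf0 + n_surface)),
        name=name,
    )


def published_scheme() -> LandmarkScheme:
    """The published femoral scheme: 20 anatomical + 176 curve + 229 surface.

    425 landmarks in total. 24 of the 176 curve semilandmarks form the two
    12-point shaft delimitation rings (stripped before shape statistics); the
    per-landmark anatomical definitions live in the study's supplementary
    material and are not reproduced, so positions are scheme-agnostic here.
    """
    return make_scheme(20, 176, 229, n_delimitation=24, points_per_chain=8,
                       name="archosauriform-femur-425")


def small_scheme() -> LandmarkScheme:
    """Reduced 5/20/30 scheme used for fast synthetic experiments."""
    return make_scheme(5, 20, 30, n_delimitation=6, points_per_chain=7,
                       name="small-femur-55")


@dataclass
class LandmarkConfiguration:
    """One specimen's digitized landmarks: a k x 3 coordinate block (mm)."""

    specimen_id: str
    coords: np.ndarray
    scheme: LandmarkScheme
    side: str = "right"
    mirrored: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be k x 3")
        if self.coords.shape[0] != self.scheme.n_total:
            raise ValueError(
                f"{self.specimen_id}: {self.coords.shape[0]} landmarks, "
                f"scheme {self.scheme.name!r} expects {self.scheme.n_total}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"{self.specimen_id}: non-finite coordinates")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be left/right, got {self.side!r}")

    @property
    def k(self) -> int:
        return self.coords.shape[0]

    def copy(self, **changes) -> "LandmarkConfiguration":
        out = replace(self, **changes)
        if "coords" not in changes:
            out.coords = self.coords.copy()
        return out


@dataclass
class TriangleMesh:
    """Triangle surface mesh in millimetres."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        if len(self.faces) == 0 or len(self.vertices) == 0:
            raise ValueError("empty mesh")
        if self.faces.max() >= len(self.vertices):
            raise ValueError("face index out of range")

    def to_trimesh(self):
        import trimesh

        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    @classmethod
    def from_trimesh(cls, mesh) -> "TriangleMesh":
        return cls(vertices=np.asarray(mesh.vertices, dtype=float),
                   faces=np.asarray(mesh.faces, dtype=int))

    @property
    def bbox_diagonal(self) -> float:
        return float(np.linalg.norm(self.vertices.max(0) - self.vertices.min(0)))


@dataclass
class SpecimenRecord:
    """One femur's metadata row (clade, locomotor mode, length, ...)."""

    specimen_id: str
    species: str
    clade: str  # pseudosuchian | avemetatarsalian | non-archosaurian
    input_mode: str  # B | Q | I
    femoral_length: float | None = None
    side: str = "right"
    juvenile: bool = False
    mdc: float | None = None
    digitization: str = ""

    def __post_init__(self) -> None:
        if self.input_mode not in ("B", "Q", "I"):
            raise ValueError(f"unknown locomotor mode code {self.input_mode!r}")
        if self.clade not in ("pseudosuchian", "avemetatarsalian", "non-archosaurian"):
            raise ValueError(f"unknown clade {self.clade!r}")
        if self.femoral_length is not None and not self.femoral_length > 0:
            raise ValueError("femoral_length must be positive")
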