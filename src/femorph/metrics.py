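"""Landmark-derived angles, shaft circumference, and allometric regressions.

Two femoral angles discriminate locomotor modes: the rotation of the femoral
head relative to the distal epiphysis (medial "twist"; bipeds cluster near
45 degrees, quadrupeds higher), and the angle between the crista
tibiofibularis and the lateral condyle in distal view. Both are measured
between two landmark-pair axes projected onto the plane orthogonal to the
bone's long (proximodistal) axis — the reproducible surrogate for measuring
on screen in a fixed view. The minimum diaphyseal circumference (MDC) is the
classic body-mass proxy extracted from mesh cross-sections; the regression of
log MDC on log centroid size validates centroid size as the size variable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .landmarks import LandmarkConfiguration, TriangleMesh

log = logging.getLogger(__name__)


@dataclass
class AngleMeasurement:
    specimen_id: str
    angle_type: str           # head_rotation | condyle_ctf | custom
    degrees: float
    landmarks: tuple[int, int, int, int]
    projected: bool


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    group: str = "all"
    slope_ci: tuple[float, float] | None = None


# ---------------------------------------------------------------------------
# angles
# ---------------------------------------------------------------------------

def _long_axis(coords: np.ndarray) -> np.ndarray:
    """First principal axis of the configuration (the proximodistal axis)."""
    centred = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    return vt[0]


def projected_axis_angle(
    config: LandmarkConfiguration | np.ndarray,
    axis1: tuple[int, int],
    axis2: tuple[int, int],
    projection: str = "long-axis-normal",
    fold: bool = True,
    angle_type: str = "custom",
    specimen_id: str | None = None,
) -> AngleMeasurement:
    """Angle between two landmark-pair axes, optionally in the cross-sectional plane.

    Parameters
    ----------
    axis1, axis2:
        Landmark index pairs defining the two segment directions.
    projection:
        ``"long-axis-normal"`` projects both directions onto the plane
        orthogonal to the configuration's first principal axis before
        measuring; ``"none"`` measures in 3D.
    fold:
        Fold the angle into [0, 90] via the absolute dot product (default);
        otherwise the range is [0, 180).
    """
    coords = config.coords if isinstance(config, LandmarkConfiguration) else np.asarray(config, float)
    sid = specimen_id or (config.specimen_id if isinstance(config, LandmarkConfiguration) else "")
    idx = (*axis1, *axis2)
    if len(set(axis1)) < 2 or len(set(axis2)) < 2:
        raise ValueError("each axis needs two distinct landmarks")
    v1 = coords[axis1[1]] - coords[axis1[0]]
    v2 = coords[axis2[1]] - coords[axis2[0]]
    if projection == "long-axis-normal":
        normal = _long_axis(coords)
        v1 = v1 - (v1 @ normal) * normal
        v2 = v2 - (v2 @ normal) * normal
    elif projection != "none":
        raise ValueError(f"unknown projection {projection!r}")
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    scale = np.linalg.norm(np.ptp(coords, axis=0))
    if n1 < 1e-12 * scale or n2 < 1e-12 * scale:
        raise ValueError("zero-length segment (possibly parallel to the projection axis)")
    cosang = float(v1 @ v2 / (n1 * n2))
    if fold:
        cosang = abs(cosang)
    degrees = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    return AngleMeasurement(specimen_id=sid, angle_type=angle_type,
                            degrees=degrees, landmarks=idx,
                            projected=projection != "none")


def angle_group_test(angles_b, angles_q, force_welch: bool = False) -> dict:
    """Two-group comparison of angle samples: F-test for equal variances, then t.

    Student's pooled-variance t is used when the variance F-test does not
    reject at 0.05, Welch's t otherwise (``force_welch`` always uses Welch).
    Two-sided p-values throughout.
    """
    a = np.asarray(angles_b, float)
    b = np.asarray(angles_q, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if np.allclose(a.mean(), b.mean()):
            return {"f_statistic": 1.0, "f_p": 1.0, "equal_var": True,
                    "t_statistic": 0.0, "t_p": 1.0, "test": "student",
                    "mean_b": float(a.mean()), "mean_q": float(b.mean())}
        raise ValueError("zero variance in both groups")
    f = va / vb if vb > 0 else np.inf
    dfa, dfb = len(a) - 1, len(b) - 1
    f_p = 2 * min(stats.f.cdf(f, dfa, dfb), stats.f.sf(f, dfa, dfb))
    equal_var = (not force_welch) and f_p > 0.05
    t, t_p = stats.ttest_ind(a, b, equal_var=equal_var)
    return {"f_statistic": float(f), "f_p": float(f_p), "equal_var": bool(equal_var),
            "t_statistic": float(t), "t_p": float(t_p),
            "test": "student" if equal_var else "welch",
            "mean_b": float(a.mean()), "mean_q": float(b.mean())}


# ---------------------------------------------------------------------------
# minimum diaphyseal circumference
# ---------------------------------------------------------------------------

def min_diaphyseal_circumference(
    mesh: TriangleMesh,
    shaft_axis: np.ndarray | None = None,
    station_range: tuple[float, float] = (0.2, 0.8),
    n_stations: int = 100,
) -> dict:
    """Minimum cross-sectional perimeter of the shaft.

    Station planes orthogonal to ``shaft_axis`` (default: the mesh's first
    principal axis) are swept across ``station_range`` (fractions of the
    axis extent, default the central 60%); at each station the mesh-plane
    intersection's longest closed loop contributes its perimeter, and the
    minimum over stations is returned with its position.
    """
    tm = mesh.to_trimesh()
    verts = np.asarray(tm.vertices)
    if shaft_axis is None:
        centred = verts - verts.mean(axis=0)
        _, _, vt = np.linalg.svd(centred, full_matrices=False)
        shaft_axis = vt[0]
    axis = np.asarray(shaft_axis, float)
    axis = axis / np.linalg.norm(axis)
    proj = verts @ axis
    lo, hi = proj.min(), proj.max()
    s0 = lo + station_range[0] * (hi - lo)
    s1 = lo + station_range[1] * (hi - lo)
    stations = np.linspace(s0, s1, int(n_stations))
    centre = verts.mean(axis=0)

    best = None
    skipped = 0
    for s in stations:
        origin = centre + (s - centre @ axis) * axis
        section = tm.section(plane_origin=origin, plane_normal=axis)
        if section is None or len(section.entities) == 0:
            skipped += 1
            continue
        perims = []
        for ent in section.entities:
            pts = section.vertices[ent.points]
            perims.append(float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()))
        perim = max(perims)
        if best is None or perim < best[0]:
            best = (perim, float(s))
    if skipped:
        log.warning("MDC: %d/%d stations had empty sections", skipped, len(stations))
    if best is None:
        raise ValueError("no station plane intersected the mesh")
    return {"mdc": best[0], "station": best[1], "n_stations": int(n_stations),
            "skipped": skipped}


# ---------------------------------------------------------------------------
# regressions
# ---------------------------------------------------------------------------

def log_log_regression(x, y, group: str = "all") -> RegressionResult:
    """OLS of log y on log x with Pearson r-squared and two-sided p."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need matched samples with n >= 3")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("log-log regression needs strictly positive values")
    return linear_regression(np.log(x), np.log(y), group=group)


def linear_regression(x, y, group: str = "all") -> RegressionResult:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    fit = stats.linregress(x, y)
    n = len(x)
    # 95% CI on the slope
    tcrit = stats.t.ppf(0.975, n - 2) if n > 2 else np.inf
    ci = (fit.slope - tcrit * fit.stderr, fit.slope + tcrit * fit.stderr)
    return RegressionResult(slope=float(fit.slope), intercept=float(fit.intercept),
                            r_squared=float(fit.rvalue ** 2),
                            p_value=float(fit.pvalue), n=n, group=group,
                            slope_ci=(float(ci[0]), float(ci[1])))


def shape_allometry_vector(flat_shapes: np.ndarray, log_cs: np.ndarray,
                           n_boot: int = 199, seed: int | None = None) -> dict:
    """Multivariate allometric regression of shape on log centroid size.

    Regresses the vectorized aligned coordinates on centered log centroid size
    in one multivariate OLS; the coefficient vector is the allometric
    component and its Euclidean norm the allometric slope magnitude (per unit
    log size). The 95% CI comes from a specimen bootstrap of the coefficient
    vector's signed projection onto the full-sample direction, which avoids
    the upward bias a norm statistic picks up under resampling.
    """
    X = np.asarray(flat_shapes, float)
    logc = np.asarray(log_cs, float)
    logc = logc - logc.mean()
    n = X.shape[0]
    if n < 4:
        raise ValueError("need at least 4 specimens")

    def coef(Xs, lc):
        lc = lc - lc.mean()
        return (lc @ (Xs - Xs.mean(0))) / (lc @ lc)

    b = coef(X, logc)
    slope = float(np.linalg.norm(b))
    direction = b / slope if slope > 0 else b
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        lc = logc[idx]
        if np.ptp(lc) <= 0:
            continue
        boots.append(float(coef(X[idx], lc) @ direction))
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return {"slope": slope, "vector": b, "ci": (float(lo), float(hi)),
            "n_boot": len(boots)}


def groupwise_allometry(scores_axis, log_cs, groups,
                        min_group_n: int = 3) -> dict[str, RegressionResult]:
    """Per-group and pooled regression of axis scores on log centroid size.

    Groups with fewer than ``min_group_n`` specimens are skipped with a log
    notice. Returns a dict keyed by group label plus ``"pooled"``.
    """
    scores = np.asarray(scores_axis, float)
    log_cs = np.asarray(log_cs, float)
    groups = np.asarray(groups)
    if not (len(scores) == len(log_cs) == len(groups)):
        raise ValueError("scores, sizes and groups must be matched")
    out: dict[str, RegressionResult] = {}
    for label in sorted(set(groups.tolist())):
        mask = groups == label
        if mask.sum() < min_group_n:
            log.warning("allometry: group %r has n=%d < %d, skipped",
                        label, int(mask.sum()), min_group_n)
            continue
        out[label] = linear_regression(log_cs[mask], scores[mask], group=str(label))
    out["pooled"] = linear_regression(log_cs, scores, group="pooled")
    return out
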