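"""Angle measurement, group tests, MDC extraction, allometric regressions."""

import numpy as np
import pytest
from scipy import stats

from femorph.landmarks import LandmarkConfiguration
from femorph.metrics import (angle_group_test, groupwise_allometry,
                             linear_regression, log_log_regression,
                             min_diaphyseal_circumference, projected_axis_angle)
from femorph.synthetic import make_test_mesh


def _angle_config(theta_deg):
    """Elongated configuration (long axis = z) with two landmark-pair axes in
    the xy plane separated by a known angle about the long axis."""
    t = np.radians(theta_deg)
    # anchors on the z axis dominate the variance and carry no xy signal, so
    # the configuration's first principal axis is exactly z
    pts = np.array([
        [0, 0, -5], [0, 0, 5],                      # long axis anchors
        [0, 0, 0], [1, 0, 0],                       # axis1 along +x
        [0, 0, 0], [np.cos(t), np.sin(t), 0],       # axis2 rotated by theta
        [0.3, -0.2, 0.0], [-0.4, 0.1, 0.0],
    ])
    from femorph.landmarks import LandmarkScheme

    scheme = LandmarkScheme(n_total=8, roles=("anatomical",) * 8)
    return LandmarkConfiguration("ang", pts, scheme)


class TestProjectedAngle:
    def test_known_rotation_about_long_axis(self):
        cfg = _angle_config(45.0)
        m = projected_axis_angle(cfg, (2, 3), (4, 5))
        assert m.degrees == pytest.approx(45.0, abs=1e-6)

    def test_same_axis_is_zero(self):
        cfg = _angle_config(45.0)
        assert projected_axis_angle(cfg, (2, 3), (2, 3)).degrees == pytest.approx(0.0, abs=1e-9)

    def test_fold_flag_range(self):
        cfg = _angle_config(135.0)
        folded = projected_axis_angle(cfg, (2, 3), (4, 5), fold=True)
        unfolded = projected_axis_angle(cfg, (2, 3), (4, 5), fold=False)
        assert folded.degrees == pytest.approx(45.0, abs=1e-6)
        assert unfolded.degrees == pytest.approx(135.0, abs=1e-6)

    def test_matches_extended_precision_oracle(self):
        rng = np.random.default_rng(59)
        pts = rng.normal(size=(8, 3))
        pts[:, 2] *= 10  # stretch z so the long axis is unambiguous
        from femorph.landmarks import LandmarkScheme

        cfg = LandmarkConfiguration(
            "o", pts, LandmarkScheme(n_total=8, roles=("anatomical",) * 8))
        m = projected_axis_angle(cfg, (0, 1), (2, 3), fold=False)
        # brute force in long double: project, normalize, arccos
        pl = pts.astype(np.longdouble)
        centred = pl - pl.mean(0)
        _, _, vt = np.linalg.svd(centred.astype(float), full_matrices=False)
        nrm = vt[0].astype(np.longdouble)
        v1 = pl[1] - pl[0]
        v2 = pl[3] - pl[2]
        v1 -= (v1 @ nrm) * nrm
        v2 -= (v2 @ nrm) * nrm
        cosang = float(v1 @ v2 / np.sqrt((v1 @ v1) * (v2 @ v2)))
        expected = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
        assert m.degrees == pytest.approx(float(expected), abs=1e-9)

    def test_rigid_motion_and_scale_invariance(self):
        cfg = _angle_config(30.0)
        base = projected_axis_angle(cfg, (2, 3), (4, 5)).degrees
        rng = np.random.default_rng(3)
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(Q) < 0:
            Q[:, 0] *= -1
        moved = cfg.copy(coords=cfg.coords @ Q.T * 7.3 + rng.normal(size=3))
        assert projected_axis_angle(moved, (2, 3), (4, 5)).degrees == pytest.approx(
            base, abs=1e-6)

    def test_zero_length_segment_rejected(self):
        cfg = _angle_config(10.0)
        with pytest.raises(ValueError):
            projected_axis_angle(cfg, (2, 2), (4, 5))
        # segment parallel to the long axis projects to ~zero
        with pytest.raises(ValueError):
            projected_axis_angle(cfg, (0, 1), (4, 5))


class TestAngleGroupTest:
    def test_identical_groups(self):
        a = np.array([44.0, 46.0, 45.0, 45.5])
        out = angle_group_test(a, a.copy())
        assert out["t_statistic"] == pytest.approx(0.0, abs=1e-12)
        assert out["t_p"] == pytest.approx(1.0)

    def test_swapping_groups_flips_sign_only(self):
        rng = np.random.default_rng(61)
        a = rng.normal(45, 5, size=20)
        b = rng.normal(60, 5, size=25)
        o1 = angle_group_test(a, b)
        o2 = angle_group_test(b, a)
        assert o1["t_statistic"] == pytest.approx(-o2["t_statistic"], rel=1e-12)
        assert o1["t_p"] == pytest.approx(o2["t_p"], rel=1e-12)

    def test_power_on_separated_groups(self):
        """N(45, 5) vs N(60, 5), n=30: the F-then-t procedure rejects at 0.01
        in nearly every replicate."""
        rng = np.random.default_rng(61)
        rejections = 0
        for _ in range(200):
            a = rng.normal(45, 5, size=30)
            b = rng.normal(60, 5, size=30)
            out = angle_group_test(a, b)
            rejections += out["t_p"] < 0.01
        assert rejections >= 0.95 * 200

    def test_welch_used_when_variances_differ(self):
        rng = np.random.default_rng(7)
        a = rng.normal(45, 1, size=40)
        b = rng.normal(45, 10, size=40)
        out = angle_group_test(a, b)
        assert out["test"] == "welch"


class TestMDC:
    def test_cylinder_matches_two_pi_r(self):
        mesh = make_test_mesh("cylinder", {"radius": 10.0, "length": 100.0})
        out = min_diaphyseal_circumference(mesh, shaft_axis=[0, 0, 1],
                                           n_stations=50)
        assert out["mdc"] == pytest.approx(2 * np.pi * 10, rel=5e-3)

    def test_bulge_outside_station_range_ignored(self):
        import trimesh

        cyl = trimesh.creation.cylinder(radius=10.0, height=100.0, sections=128)
        bulge = trimesh.creation.icosphere(subdivisions=3, radius=14.0)
        bulge.apply_translation([0, 0, 45.0])  # near the top end, outside 20-80%
        combo = trimesh.util.concatenate([cyl, bulge])
        from femorph.landmarks import TriangleMesh

        mesh = TriangleMesh(vertices=np.asarray(combo.vertices),
                            faces=np.asarray(combo.faces))
        out = min_diaphyseal_circumference(mesh, shaft_axis=[0, 0, 1],
                                           station_range=(0.3, 0.6),
                                           n_stations=40)
        assert out["mdc"] == pytest.approx(2 * np.pi * 10, rel=5e-3)

    def test_scaling_doubles_mdc(self):
        mesh = make_test_mesh("cylinder", {"radius": 4.0, "length": 50.0})
        big = type(mesh)(vertices=mesh.vertices * 2.0, faces=mesh.faces)
        a = min_diaphyseal_circumference(mesh, shaft_axis=[0, 0, 1], n_stations=30)
        b = min_diaphyseal_circumference(big, shaft_axis=[0, 0, 1], n_stations=30)
        assert b["mdc"] == pytest.approx(2 * a["mdc"], rel=1e-9)


class TestRegressions:
    def test_exact_power_law(self):
        x = np.linspace(1.0, 50.0, 20)
        y = 2.0 * x ** 1.5
        fit = log_log_regression(x, y)
        assert fit.slope == pytest.approx(1.5, abs=1e-12)
        assert fit.intercept == pytest.approx(np.log(2.0), abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_independent_y_gives_null_behaviour(self):
        rng = np.random.default_rng(67)
        x = rng.uniform(1, 10, size=100)
        y = rng.uniform(1, 10, size=100)
        fit = log_log_regression(x, y)
        assert fit.r_squared < 0.1

    def test_permutation_invariance_to_point_order(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(1, 5, size=30)
        y = np.exp(0.5 + 0.8 * np.log(x)) * rng.lognormal(0, 0.1, 30)
        f1 = log_log_regression(x, y)
        perm = rng.permutation(30)
        f2 = log_log_regression(x[perm], y[perm])
        assert f1.slope == pytest.approx(f2.slope, rel=1e-12)
        assert f1.r_squared == pytest.approx(f2.r_squared, rel=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            log_log_regression([1.0, -2.0, 3.0], [1.0, 2.0, 3.0])

    def test_null_pvalues_uniform(self):
        """Regression p-values under the null are U(0,1) (KS check)."""
        rng = np.random.default_rng(9)
        pvals = [linear_regression(rng.normal(size=20), rng.normal(size=20)).p_value
                 for _ in range(500)]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestGroupwiseAllometry:
    def test_perfect_line_single_group(self):
        x = np.linspace(0, 1, 10)
        out = groupwise_allometry(2.0 * x + 1.0, x, ["B"] * 10)
        assert out["B"].r_squared == pytest.approx(1.0)
        assert out["B"].slope == pytest.approx(2.0)

    def test_slope_recovered_in_group_b_only(self):
        """Group B has slope beta, group Q none: B's fit is stronger and the
        95% CI covers beta in >= 90% of replicates."""
        beta = 0.8
        rng = np.random.default_rng(71)
        covered = 0
        stronger = 0
        n_rep = 100
        for _ in range(n_rep):
            x = rng.uniform(0, 2, size=120)
            g = np.array(["B"] * 60 + ["Q"] * 60)
            y = np.where(g == "B", beta * x, 0.0) + rng.normal(0, 0.4, 120)
            out = groupwise_allometry(y, x, g)
            lo, hi = out["B"].slope_ci
            covered += lo <= beta <= hi
            stronger += out["B"].r_squared > out["Q"].r_squared
        assert covered >= 0.9 * n_rep
        assert stronger >= 0.95 * n_rep

    def test_small_group_skipped(self):
        out = groupwise_allometry([1.0, 2, 3, 4], [0.0, 1, 2, 3],
                                  ["B", "B", "B", "Q"])
        assert "Q" not in out and "B" in out and "pooled" in out
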