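import numpy as np
import pytest

from morphanat.io import TriSurface
from morphanat.quality import (
    DEFAULT_GATES,
    GeometricErrorReport,
    QualityReport,
    point_surface_distances,
    quality_change_rate,
    scaled_jacobian,
    skew,
    surface_distance_error,
    validate_morph,
)

UNIT_CUBE = np.array([
    [0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
    [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1],
], dtype=float)

_HEXA_TRIADS = ((1, 3, 4), (2, 0, 5), (3, 1, 6), (0, 2, 7),
                (7, 5, 0), (4, 6, 1), (5, 7, 2), (6, 4, 3))


def oracle_hexa_scaled_jacobian(corners):
    """Independent brute-force per-corner determinant evaluation."""
    vals = []
    for i, (a, b, c) in enumerate(_HEXA_TRIADS):
        e = np.array([corners[a] - corners[i],
                      corners[b] - corners[i],
                      corners[c] - corners[i]])
        vals.append(np.linalg.det(e) / np.prod(np.linalg.norm(e, axis=1)))
    return min(vals)


def oracle_point_triangle(p, a, b, c):
    """Ericson closed-form closest point on triangle (scalar, per pair)."""
    ab, ac, ap = b - a, c - a, p - a
    d1, d2 = ab @ ap, ac @ ap
    if d1 <= 0 and d2 <= 0:
        return np.linalg.norm(p - a)
    bp = p - b
    d3, d4 = ab @ bp, ac @ bp
    if d3 >= 0 and d4 <= d3:
        return np.linalg.norm(p - b)
    vc = d1 * d4 - d3 * d2
    if vc <= 0 and d1 >= 0 and d3 <= 0:
        v = d1 / (d1 - d3)
        return np.linalg.norm(p - (a + v * ab))
    cp = p - c
    d5, d6 = ab @ cp, ac @ cp
    if d6 >= 0 and d5 <= d6:
        return np.linalg.norm(p - c)
    vb = d5 * d2 - d1 * d6
    if vb <= 0 and d2 >= 0 and d6 <= 0:
        w = d2 / (d2 - d6)
        return np.linalg.norm(p - (a + w * ac))
    va = d3 * d6 - d5 * d4
    if va <= 0 and (d4 - d3) >= 0 and (d5 - d6) >= 0:
        w = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        return np.linalg.norm(p - (b + w * (c - b)))
    denom = 1.0 / (va + vb + vc)
    v, w = vb * denom, vc * denom
    return np.linalg.norm(p - (a + ab * v + ac * w))


def _rotation(axis, angle):
    axis = np.asarray(axis, dtype=float)
    axis /= np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * K @ K


class TestScaledJacobian:
    def test_unit_cube_is_one(self):
        assert scaled_jacobian(UNIT_CUBE, "solid") == pytest.approx(1.0)

    def test_sheared_cube_matches_corner_oracle(self, rng):
        sheared = UNIT_CUBE + 0.3 * rng.normal(size=(8, 3))
        got = scaled_jacobian(sheared, "solid")
        assert got == pytest.approx(oracle_hexa_scaled_jacobian(sheared), abs=1e-12)

    def test_coincident_corners_degenerate(self):
        bad = UNIT_CUBE.copy()
        bad[1] = bad[0]
        assert scaled_jacobian(bad, "solid") <= 0.0

    def test_regular_tet(self):
        tet = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
        # corner triads: corner 0 is orthonormal (det 1), others are not
        val = scaled_jacobian(tet, "solid")
        assert 0 < val < 1

    def test_unit_square_quad_shell(self):
        quad = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], float)
        assert scaled_jacobian(quad, "shell") == pytest.approx(1.0)

    def test_inverted_quad_negative(self):
        bowtie = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], float)
        assert scaled_jacobian(bowtie, "shell") < 0

    def test_rigid_invariance(self, rng):
        R = _rotation([1, 1, 0], 1.2)
        t = np.array([5.0, -2.0, 9.0])
        sheared = UNIT_CUBE + 0.2 * rng.normal(size=(8, 3))
        a = scaled_jacobian(sheared, "solid")
        b = scaled_jacobian(sheared @ R.T + t, "solid")
        assert b == pytest.approx(a, abs=1e-9)


class TestSkew:
    def test_unit_square_zero(self):
        quad = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], float)
        assert skew(quad, "shell") == pytest.approx(0.0, abs=1e-12)

    def test_equilateral_triangle_zero(self):
        tri = np.array([[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0]], float)
        assert skew(tri, "shell") == pytest.approx(0.0, abs=1e-12)

    def test_parallelogram_closed_form(self):
        # angles 60/120 degrees -> (120 - 90) / 90 = 1/3
        para = np.array([[0, 0, 0], [1, 0, 0],
                         [1.5, np.sqrt(3) / 2, 0], [0.5, np.sqrt(3) / 2, 0]])
        assert skew(para, "shell") == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_degenerate_collinear_is_one(self):
        tri = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], float)
        assert skew(tri, "shell") == pytest.approx(1.0)

    def test_cube_zero_regular_tet_zero(self):
        assert skew(UNIT_CUBE, "solid") == pytest.approx(0.0, abs=1e-12)
        reg_tet = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], float)
        assert skew(reg_tet, "solid") == pytest.approx(0.0, abs=1e-12)

    def test_rigid_invariance(self, rng):
        R = _rotation([0, 1, 1], 0.8)
        sheared = UNIT_CUBE + 0.2 * rng.normal(size=(8, 3))
        assert skew(sheared @ R.T + 3.0, "solid") == pytest.approx(
            skew(sheared, "solid"), abs=1e-9)


class TestChangeRates:
    def test_identity_morph_zero_rates(self, baseline_mesh):
        mesh, _ = baseline_mesh
        rep = quality_change_rate(mesh, mesh.with_coords(mesh.node_coords))
        assert rep.mean_change_rate == 0.0
        assert rep.max_change_rate == 0.0

    def test_rigid_motion_zero_rates(self, baseline_mesh):
        mesh, _ = baseline_mesh
        R = _rotation([1, 2, 3], 0.9)
        moved = mesh.with_coords(mesh.node_coords @ R.T + np.array([3.0, 4.0, 5.0]))
        rep = quality_change_rate(mesh, moved)
        assert rep.max_change_rate < 1e-9

    def test_uniform_scaling_zero_rates(self, baseline_mesh):
        mesh, _ = baseline_mesh
        scaled = mesh.with_coords(1.1 * mesh.node_coords)
        rep = quality_change_rate(mesh, scaled)
        assert rep.max_change_rate < 1e-9
        # cross-check one element by direct recomputation on scaled coords
        row = mesh.solids[0]
        base = scaled_jacobian(mesh.coords_of(row[2:10]), "solid")
        after = scaled_jacobian(1.1 * mesh.coords_of(row[2:10]), "solid")
        assert after == pytest.approx(base, abs=1e-12)

    def test_connectivity_mismatch_raises(self, baseline_mesh):
        from morphanat.io import FEMesh

        mesh, _ = baseline_mesh
        other = FEMesh(node_ids=mesh.node_ids, node_coords=mesh.node_coords,
                       shells=mesh.shells[:-1], solids=mesh.solids,
                       landmark_set=mesh.landmark_set)
        with pytest.raises(ValueError, match="connectivity"):
            quality_change_rate(mesh, other)

    def test_summary_split_by_dimension(self, baseline_mesh):
        mesh, _ = baseline_mesh
        rep = quality_change_rate(mesh, mesh.with_coords(mesh.node_coords))
        assert set(rep.change_summary) == {"2d", "3d"}
        assert rep.summary["3d"]["min_jacobian"] == pytest.approx(1.0)


class TestSurfaceDistance:
    def test_nodes_on_surface_zero(self, baseline_mesh):
        mesh, surf = baseline_mesh
        rep = surface_distance_error(mesh, 1, surf)
        assert rep.max_error < 1e-9
        assert rep.mean_error <= rep.max_error

    def test_height_above_large_triangle(self):
        tri = TriSurface(vertices=[[-10, -10, 0], [10, -10, 0], [0, 10, 0]],
                         triangles=[[0, 1, 2]])
        h = 2.5
        d = point_surface_distances(np.array([[0.0, 0.0, h]]), tri)
        assert d[0] == pytest.approx(h, abs=1e-12)

    def test_matches_exhaustive_scalar_oracle(self, rng, baseline_mesh):
        _, surf = baseline_mesh  # 432 triangles
        pts = rng.uniform(-120, 120, size=(50, 3))
        got = point_surface_distances(pts, surf)
        corners = surf.triangle_corners()
        for i, p in enumerate(pts):
            expected = min(oracle_point_triangle(p, *tri) for tri in corners)
            assert got[i] == pytest.approx(expected, abs=1e-9)

    def test_empty_part_raises(self, baseline_mesh):
        mesh, surf = baseline_mesh
        with pytest.raises(ValueError, match="no nodes"):
            surface_distance_error(mesh, 99, surf)


class TestGates:
    def _reports(self, **overrides):
        q = QualityReport(per_element_jacobian={1: overrides.get("jac", 0.9)},
                          per_element_skew={1: 0.1},
                          summary={},
                          change_rates={1: {"jacobian": overrides.get("rate", 0.0),
                                            "skew": 0.0}})
        g = GeometricErrorReport(per_node_distance={},
                                 mean_error=overrides.get("mean", 0.0),
                                 max_error=overrides.get("max", 0.0))
        return q, g

    def test_identity_passes(self):
        q, g = self._reports()
        verdict = validate_morph(q, g)
        assert verdict.passed and not verdict.failures

    def test_max_change_gate_fires(self):
        q, g = self._reports(rate=0.12)
        verdict = validate_morph(q, g)
        assert not verdict.passed
        assert any("max quality change" in f for f in verdict.failures)

    def test_jacobian_gate_fires(self):
        q, g = self._reports(jac=0.19)
        verdict = validate_morph(q, g)
        assert not verdict.passed
        assert any("Jacobian" in f for f in verdict.failures)

    def test_geometric_gates_fire(self):
        q, g = self._reports(mean=4.5, max=6.0)
        verdict = validate_morph(q, g)
        assert sum("geometric error" in f for f in verdict.failures) == 2

    def test_relaxing_gates_never_flips_pass_to_fail(self):
        q, g = self._reports(rate=0.07, jac=0.25, mean=3.0, max=4.5)
        strict = validate_morph(q, g, DEFAULT_GATES)
        relaxed = validate_morph(q, g, {
            "mean_error_mm": 8.0, "max_error_mm": 10.0,
            "mean_change_rate": 0.2, "max_change_rate": 0.2,
            "min_scaled_jacobian": 0.1,
        })
        assert relaxed.passed
        assert len(relaxed.failures) <= len(strict.failures)
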