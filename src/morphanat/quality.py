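"""Morph-fidelity validation: mesh quality and geometric error.

Quality metrics follow the common FE preprocessing definitions:

* scaled Jacobian — per corner, the determinant of the corner edge triad
  (solids) or the normalized corner cross product signed by the element
  normal (shells), normalized by the edge lengths; the element value is the
  corner minimum. 1 for ideal elements, <= 0 for degenerate/inverted.
* equiangular skew — max over interior angles theta of
  max((theta - theta_e)/(180 - theta_e), (theta_e - theta)/theta_e) with
  theta_e = 90 deg for quad faces and 60 deg for triangle faces; solids take
  the max over their faces. 0 for ideal, 1 for degenerate.

Morph fidelity is judged by per-element relative change rates of both
metrics against the baseline mesh, and by exact point-to-surface distances
from the skull surface nodes to a target triangulated surface. Default
acceptance gates: mean geometric error < 4 mm, max < 5 mm, mean quality
change < 5%, max change < 10%, minimum scaled Jacobian > 0.2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import FEMesh, TriSurface

__all__ = [
    "scaled_jacobian",
    "skew",
    "element_quality_tables",
    "QualityReport",
    "GeometricErrorReport",
    "Verdict",
    "DEFAULT_GATES",
    "quality_change_rate",
    "point_surface_distances",
    "surface_distance_error",
    "validate_morph",
]

# corner -> (neighbor_a, neighbor_b, neighbor_c) giving a right-handed edge
# triad with determinant +1 on the unit cube (standard hexa node ordering:
# nodes 1-4 bottom face, 5-8 top face)
_HEXA_TRIADS = ((1, 3, 4), (2, 0, 5), (3, 1, 6), (0, 2, 7),
                (7, 5, 0), (4, 6, 1), (5, 7, 2), (6, 4, 3))
_TET_TRIADS = ((1, 2, 3), (2, 0, 3), (0, 1, 3), (0, 2, 1))

_HEXA_FACES = ((0, 1, 2, 3), (4, 7, 6, 5), (0, 4, 5, 1),
               (1, 5, 6, 2), (2, 6, 7, 3), (3, 7, 4, 0))
_TET_FACES = ((0, 1, 2), (0, 1, 3), (1, 2, 3), (0, 2, 3))

DEFAULT_GATES = {
    "mean_error_mm": 4.0,
    "max_error_mm": 5.0,
    "mean_change_rate": 0.05,
    "max_change_rate": 0.10,
    "min_scaled_jacobian": 0.2,
}


def _solid_scaled_jacobian(corners: np.ndarray) -> float:
    n = len(corners)
    triads = _TET_TRIADS if n == 4 else _HEXA_TRIADS
    best = np.inf
    for i, (a, b, c) in enumerate(triads):
        e = np.stack([corners[a] - corners[i],
                      corners[b] - corners[i],
                      corners[c] - corners[i]])
        norms = np.linalg.norm(e, axis=1)
        if (norms < 1e-14).any():
            return -1.0  # zero-length edge: degenerate
        best = min(best, float(np.linalg.det(e) / norms.prod()))
    return best


def _shell_scaled_jacobian(corners: np.ndarray) -> float:
    n = len(corners)
    # element normal from the corner cross products (average orientation)
    crosses = []
    for i in range(n):
        e1 = corners[(i + 1) % n] - corners[i]
        e2 = corners[(i - 1) % n] - corners[i]
        crosses.append(np.cross(e1, e2))
    normal = np.sum(crosses, axis=0)
    nn = np.linalg.norm(normal)
    if nn < 1e-14:
        return -1.0
    normal /= nn
    best = np.inf
    for i in range(n):
        e1 = corners[(i + 1) % n] - corners[i]
        e2 = corners[(i - 1) % n] - corners[i]
        l1, l2 = np.linalg.norm(e1), np.linalg.norm(e2)
        if l1 < 1e-14 or l2 < 1e-14:
            return -1.0
        best = min(best, float(np.dot(np.cross(e1, e2), normal) / (l1 * l2)))
    return best


def scaled_jacobian(corners: np.ndarray, element_class: str) -> float:
    """Corner scaled Jacobian of one element.

    ``corners`` is (3 or 4) x 3 for shells, (4 or 8) x 3 for solids.
    Degenerate elements (zero-length edges) return -1.0 instead of raising.
    """
    corners = np.asarray(corners, dtype=float)
    if element_class == "shell":
        if len(corners) not in (3, 4):
            raise ValueError("shell elements have 3 or 4 corners")
        return _shell_scaled_jacobian(corners)
    if element_class == "solid":
        if len(corners) not in (4, 8):
            raise ValueError("solid elements have 4 or 8 corners")
        return _solid_scaled_jacobian(corners)
    raise ValueError(f"unknown element class {element_class!r}")


def _face_skew(face: np.ndarray) -> float:
    n = len(face)
    theta_e = 90.0 if n == 4 else 60.0
    worst = 0.0
    for i in range(n):
        e1 = face[(i + 1) % n] - face[i]
        e2 = face[(i - 1) % n] - face[i]
        l1, l2 = np.linalg.norm(e1), np.linalg.norm(e2)
        if l1 < 1e-14 or l2 < 1e-14:
            return 1.0
        cosang = np.clip(np.dot(e1, e2) / (l1 * l2), -1.0, 1.0)
        theta = np.degrees(np.arccos(cosang))
        worst = max(worst,
                    (theta - theta_e) / (180.0 - theta_e),
                    (theta_e - theta) / theta_e)
    return float(min(worst, 1.0))


def skew(corners: np.ndarray, element_class: str) -> float:
    """Equiangular skew of one element (max over faces for solids)."""
    corners = np.asarray(corners, dtype=float)
    if element_class == "shell":
        if len(corners) not in (3, 4):
            raise ValueError("shell elements have 3 or 4 corners")
        return _face_skew(corners)
    if element_class == "solid":
        if len(corners) not in (4, 8):
            raise ValueError("solid elements have 4 or 8 corners")
        faces = _TET_FACES if len(corners) == 4 else _HEXA_FACES
        return float(max(_face_skew(corners[list(f)]) for f in faces))
    raise ValueError(f"unknown element class {element_class!r}")


def element_quality_tables(mesh: FEMesh) -> tuple[dict[int, tuple[float, float]], dict[int, tuple[float, float]]]:
    """(shell, solid) tables: element id -> (scaled_jacobian, skew)."""
    shells: dict[int, tuple[float, float]] = {}
    counts = mesh.shell_corner_counts()
    for row, nc in zip(mesh.shells, counts):
        corners = mesh.coords_of(row[2 : 2 + nc])
        shells[int(row[0])] = (scaled_jacobian(corners, "shell"),
                               skew(corners, "shell"))
    solids: dict[int, tuple[float, float]] = {}
    counts = mesh.solid_corner_counts()
    for row, nc in zip(mesh.solids, counts):
        corners = mesh.coords_of(row[2 : 2 + nc])
        solids[int(row[0])] = (scaled_jacobian(corners, "solid"),
                               skew(corners, "solid"))
    return shells, solids


@dataclass
class QualityReport:
    per_element_jacobian: dict[int, float]
    per_element_skew: dict[int, float]
    summary: dict[str, dict[str, float]]
    change_rates: dict[int, dict[str, float]] = field(default_factory=dict)
    change_summary: dict[str, dict[str, float]] = field(default_factory=dict)

    @property
    def min_scaled_jacobian(self) -> float:
        return min(self.per_element_jacobian.values())

    @property
    def mean_change_rate(self) -> float:
        rates = [r for d in self.change_rates.values() for r in d.values()]
        return float(np.mean(rates)) if rates else 0.0

    @property
    def max_change_rate(self) -> float:
        rates = [r for d in self.change_rates.values() for r in d.values()]
        return float(np.max(rates)) if rates else 0.0


@dataclass
class GeometricErrorReport:
    per_node_distance: dict[int, float]
    mean_error: float
    max_error: float


@dataclass
class Verdict:
    passed: bool
    failures: list[str]


def _summarize(shell_tab, solid_tab) -> dict[str, dict[str, float]]:
    out: dict[str, dict[str, float]] = {}
    for cls, tab in (("2d", shell_tab), ("3d", solid_tab)):
        if not tab:
            continue
        sj = np.array([v[0] for v in tab.values()])
        sk = np.array([v[1] for v in tab.values()])
        out[cls] = {
            "min_jacobian": float(sj.min()), "mean_jacobian": float(sj.mean()),
            "max_skew": float(sk.max()), "mean_skew": float(sk.mean()),
        }
    return out


def quality_change_rate(
    baseline: FEMesh, morphed: FEMesh, floor: float = 1e-3
) -> QualityReport:
    """Per-element quality change rates of the morphed vs baseline mesh.

    rate = |q_morph - q_base| / max(|q_base|, floor) per metric; the floor
    guards near-zero baseline values (a perfect element has skew 0).
    """
    if not (np.array_equal(baseline.shells, morphed.shells)
            and np.array_equal(baseline.solids, morphed.solids)
            and np.array_equal(baseline.node_ids, morphed.node_ids)):
        raise ValueError("baseline and morphed meshes differ in connectivity")
    b_shell, b_solid = element_quality_tables(baseline)
    m_shell, m_solid = element_quality_tables(morphed)
    jac = {**{k: v[0] for k, v in m_shell.items()},
           **{k: v[0] for k, v in m_solid.items()}}
    skw = {**{k: v[1] for k, v in m_shell.items()},
           **{k: v[1] for k, v in m_solid.items()}}
    rates: dict[int, dict[str, float]] = {}
    change_summary: dict[str, dict[str, float]] = {}
    for cls, base_tab, morph_tab in (("2d", b_shell, m_shell), ("3d", b_solid, m_solid)):
        cls_rates = []
        for eid, (bj, bs) in base_tab.items():
            mj, ms = morph_tab[eid]
            rj = abs(mj - bj) / max(abs(bj), floor)
            rs = abs(ms - bs) / max(abs(bs), floor)
            rates[eid] = {"jacobian": rj, "skew": rs}
            cls_rates += [rj, rs]
        if cls_rates:
            change_summary[cls] = {"mean": float(np.mean(cls_rates)),
                                   "max": float(np.max(cls_rates))}
    return QualityReport(
        per_element_jacobian=jac,
        per_element_skew=skw,
        summary=_summarize(m_shell, m_solid),
        change_rates=rates,
        change_summary=change_summary,
    )


def point_surface_distances(points: np.ndarray, surface: TriSurface) -> np.ndarray:
    """Exact minimum point-to-triangle distance for each point.

    Vectorized exhaustive scan over all point-triangle pairs (the fixture
    scales here make an index unnecessary, and the exhaustive result is the
    reference the accelerated variants must match anyway). The per-pair
    distance is the minimum of the in-triangle plane projection and the
    three edge-segment distances.
    """
    P = np.atleast_2d(np.asarray(points, dtype=float))  # n x 3
    tri = surface.triangle_corners()  # t x 3 x 3
    if len(tri) == 0:
        raise ValueError("target surface is empty")
    n, t = len(P), len(tri)
    best = np.full((n, t), np.inf)

    v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
    # plane projection with barycentric inside test
    e0, e1 = v1 - v0, v2 - v0
    normal = np.cross(e0, e1)  # t x 3
    nn2 = (normal ** 2).sum(axis=1)
    d = P[:, None, :] - v0[None, :, :]  # n x t x 3
    dist_plane = np.abs(np.einsum("ntk,tk->nt", d, normal)) / np.sqrt(
        np.maximum(nn2, 1e-300)
    )
    a = (e0 * e0).sum(axis=1)
    b = (e0 * e1).sum(axis=1)
    c = (e1 * e1).sum(axis=1)
    det = np.maximum(a * c - b * b, 1e-300)
    de0 = np.einsum("ntk,tk->nt", d, e0)
    de1 = np.einsum("ntk,tk->nt", d, e1)
    s = (c * de0 - b * de1) / det
    u = (a * de1 - b * de0) / det
    inside = (s >= 0) & (u >= 0) & (s + u <= 1)
    best = np.where(inside, dist_plane, best)

    # edge segments
    for pa, pb in ((v0, v1), (v1, v2), (v2, v0)):
        ab = pb - pa  # t x 3
        ab2 = np.maximum((ab ** 2).sum(axis=1), 1e-300)
        ap = P[:, None, :] - pa[None, :, :]
        tproj = np.clip(np.einsum("ntk,tk->nt", ap, ab) / ab2, 0.0, 1.0)
        closest = pa[None, :, :] + tproj[..., None] * ab[None, :, :]
        dseg = np.linalg.norm(P[:, None, :] - closest, axis=2)
        best = np.minimum(best, dseg)
    return best.min(axis=1)


def surface_distance_error(
    mesh: FEMesh, surface_part: int, target: TriSurface
) -> GeometricErrorReport:
    """Distances from every node of one part to the target surface."""
    node_ids: list[int] = []
    counts = mesh.shell_corner_counts()
    for row, nc in zip(mesh.shells, counts):
        if int(row[1]) == surface_part:
            node_ids.extend(int(v) for v in row[2 : 2 + nc])
    counts = mesh.solid_corner_counts()
    for row, nc in zip(mesh.solids, counts):
        if int(row[1]) == surface_part:
            node_ids.extend(int(v) for v in row[2 : 2 + nc])
    node_ids = sorted(set(node_ids))
    if not node_ids:
        raise ValueError(f"no nodes found for part {surface_part}")
    dists = point_surface_distances(mesh.coords_of(node_ids), target)
    return GeometricErrorReport(
        per_node_distance={nid: float(dv) for nid, dv in zip(node_ids, dists)},
        mean_error=float(dists.mean()),
        max_error=float(dists.max()),
    )


def validate_morph(
    quality: QualityReport,
    geometric: GeometricErrorReport,
    gates: dict[str, float] | None = None,
) -> Verdict:
    """Apply the morph acceptance gates; failing gates are enumerated."""
    g = dict(DEFAULT_GATES, **(gates or {}))
    failures: list[str] = []
    if geometric.mean_error >= g["mean_error_mm"]:
        failures.append(
            f"mean geometric error {geometric.mean_error:.3f} mm >= {g['mean_error_mm']} mm"
        )
    if geometric.max_error >= g["max_error_mm"]:
        failures.append(
            f"max geometric error {geometric.max_error:.3f} mm >= {g['max_error_mm']} mm"
        )
    if quality.mean_change_rate >= g["mean_change_rate"]:
        failures.append(
            f"mean quality change {quality.mean_change_rate:.2%} >= {g['mean_change_rate']:.0%}"
        )
    if quality.max_change_rate >= g["max_change_rate"]:
        failures.append(
            f"max quality change {quality.max_change_rate:.2%} >= {g['max_change_rate']:.0%}"
        )
    if quality.min_scaled_jacobian <= g["min_scaled_jacobian"]:
        failures.append(
            f"min scaled Jacobian {quality.min_scaled_jacobian:.3f} <= {g['min_scaled_jacobian']}"
        )
    return Verdict(passed=not failures, failures=failures)
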