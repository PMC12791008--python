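"""Deforming-surface morphodynamics: ICP registration, shape timelines,
covariant out-of-plane deformation 2Hv_n, and Lagrangian correlations.

Meshes are plain (vertices, faces) arrays with consistent vertex indexing
across frames of a sequence (material correspondence), which the synthetic
generator guarantees.  Mean curvature uses the cotangent Laplace–Beltrami
operator with mixed Voronoi areas; the sign convention is H > 0 for a
sphere with outward normals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import MorphalineError
from .similarity import SimilarityMatrix, _pearson

__all__ = [
    "TriMeshFrame",
    "MeshSequence",
    "RigidTransform",
    "DeformationFrame",
    "icp_register",
    "kabsch",
    "shape_similarity_matrix",
    "vertex_normals",
    "mean_curvature",
    "out_of_plane_deformation",
    "lagrangian_autocorr",
]


@dataclass
class TriMeshFrame:
    """One triangulated surface at a single time (μm, minutes)."""

    vertices: np.ndarray  # (n, 3)
    faces: np.ndarray  # (m, 3) int
    time: float = 0.0

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be an (m, 3) integer array")
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValueError("face index out of range")

    def boundary_vertices(self) -> np.ndarray:
        """Boolean mask of vertices on an open boundary (edge with one face)."""
        edges = np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        edges = np.sort(edges, axis=1)
        uniq, counts = np.unique(edges, axis=0, return_counts=True)
        mask = np.zeros(len(self.vertices), dtype=bool)
        mask[uniq[counts == 1].ravel()] = True
        return mask


@dataclass
class MeshSequence:
    """Time-ordered meshes with consistent vertex indexing."""

    frames: list

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("empty mesh sequence")
        times = [f.time for f in self.frames]
        if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, k):
        return self.frames[k]

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])


@dataclass
class RigidTransform:
    """Proper rigid motion x ↦ R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length 3")
        if np.abs(self.rotation.T @ self.rotation - np.eye(3)).max() > 1e-9:
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation must be proper (det +1)")

    def apply(self, pts: np.ndarray) -> np.ndarray:
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform x ↦ self(other(x))."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclass
class DeformationFrame:
    """Per-vertex out-of-plane deformation of a surface between two frames.

    ``d = 2 * H * v_n`` elementwise (1/min); boundary vertices are masked.
    """

    H: np.ndarray  # mean curvature, 1/μm
    v_n: np.ndarray  # normal velocity, μm/min, positive outward
    d: np.ndarray  # 2 H v_n, 1/min
    valid: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        ok = self.valid
        if not np.allclose(self.d[ok], 2.0 * self.H[ok] * self.v_n[ok], atol=1e-12):
            raise ValueError("d must equal 2*H*v_n elementwise")


# ---------------------------------------------------------------------------
# rigid registration
# ---------------------------------------------------------------------------


def kabsch(p: np.ndarray, q: np.ndarray) -> RigidTransform:
    """Closed-form least-squares rigid transform mapping p onto q (SVD)."""
    cp, cq = p.mean(axis=0), q.mean(axis=0)
    h = (p - cp).T @ (q - cq)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return RigidTransform(r, cq - r @ cp)


def _principal_axes(p: np.ndarray) -> np.ndarray:
    """Right-handed principal-axis frame of a centred point set."""
    _, _, vt = np.linalg.svd(p - p.mean(axis=0), full_matrices=False)
    axes = vt
    if np.linalg.det(axes) < 0:
        axes[2] *= -1
    return axes


def _rank_check(p: np.ndarray) -> None:
    s = np.linalg.svd(p - p.mean(axis=0), compute_uv=False)
    scale = s[0] if s[0] > 0 else 1.0
    if len(p) < 4 or s[2] / scale < 1e-9:
        raise MorphalineError("degenerate point set: need ≥ 4 non-coplanar points")


def icp_register(
    p: np.ndarray,
    q: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> tuple[RigidTransform, float]:
    """Iterative-closest-point rigid registration of p onto q.

    Initialized by centroid alignment plus a principal-axes pre-rotation
    (best of the four proper sign combinations), then alternates
    nearest-neighbour correspondence with the closed-form Kabsch fit until
    the r.m.s. residual changes by less than ``tol``.  Returns the
    recovered transform and the final r.m.s. nearest-neighbour distance.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    _rank_check(p)
    _rank_check(q)
    tree = cKDTree(q)

    def rms(x):
        d, _ = tree.query(x)
        return float(np.sqrt(np.mean(d**2)))

    ap, aq = _principal_axes(p), _principal_axes(q)
    cp, cq = p.mean(axis=0), q.mean(axis=0)
    best_init, best_res = None, np.inf
    for sx, sy in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
        flip = np.diag([sx, sy, sx * sy])  # proper rotations only
        r0 = aq.T @ flip @ ap
        t0 = cq - r0 @ cp
        cand = RigidTransform(r0, t0)
        res = rms(cand.apply(p))
        if res < best_res:
            best_init, best_res = cand, res

    transform = best_init
    prev = best_res
    converged = False
    for _ in range(max_iter):
        moved = transform.apply(p)
        _, idx = tree.query(moved)
        step = kabsch(moved, q[idx])
        transform = step.compose(transform)
        cur = rms(transform.apply(p))
        if abs(prev - cur) < tol:
            prev = cur
            converged = True
            break
        prev = cur
    if not converged:
        warnings.warn("ICP did not converge within max_iter; returning best transform")
    return transform, prev


def shape_similarity_matrix(seq_a: MeshSequence, seq_b: MeshSequence) -> SimilarityMatrix:
    """Shape-based similarity between two mesh timelines.

    Entry (i, j) is ``exp(-residual_ij / sigma_ref)`` where residual_ij is
    the post-ICP r.m.s. distance between frames and sigma_ref the median of
    all residuals, giving a monotone similarity in (0, 1] that feeds the
    monotone-shortest-path alignment and timestamping machinery.
    """
    res = np.full((len(seq_a), len(seq_b)), np.nan)
    for i, fa in enumerate(seq_a):
        for j, fb in enumerate(seq_b):
            try:
                _, r = icp_register(fa.vertices, fb.vertices)
                res[i, j] = r
            except MorphalineError:
                pass
    finite = res[np.isfinite(res)]
    if finite.size == 0:
        raise MorphalineError("all pairwise ICP registrations failed")
    sigma_ref = max(float(np.median(finite)), 1e-12)
    sim = np.exp(-res / sigma_ref)
    return SimilarityMatrix(sim, seq_a.times, seq_b.times, "icp_shape", {"sigma_ref": sigma_ref})


# ---------------------------------------------------------------------------
# curvature and out-of-plane deformation
# ---------------------------------------------------------------------------


def _face_data(mesh: TriMeshFrame):
    v = mesh.vertices
    f = mesh.faces
    e = [v[f[:, (k + 2) % 3]] - v[f[:, (k + 1) % 3]] for k in range(3)]  # edge opposite k
    cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    area2 = np.linalg.norm(cross, axis=1)  # 2 * face area
    return f, e, cross, area2


def vertex_normals(mesh: TriMeshFrame) -> np.ndarray:
    """Area-weighted outward unit vertex normals."""
    f, _, cross, _ = _face_data(mesh)
    normals = np.zeros_like(mesh.vertices)
    for k in range(3):
        np.add.at(normals, f[:, k], cross)
    norm = np.linalg.norm(normals, axis=1, keepdims=True)
    return normals / np.maximum(norm, 1e-300)


def mean_curvature(mesh: TriMeshFrame) -> tuple[np.ndarray, np.ndarray]:
    """Discrete mean curvature per vertex (1/μm) and a validity mask.

    Cotangent Laplace–Beltrami with mixed Voronoi areas (Voronoi area on
    non-obtuse triangles, area/2 at the obtuse corner and area/4 elsewhere
    on obtuse ones).  H = −(Δx · n̂)/2 so that a sphere with outward
    normals has H = 1/R.  Boundary vertices and degenerate triangles are
    flagged invalid.
    """
    v = mesh.vertices
    f, e, _, area2 = _face_data(mesh)
    n = len(v)
    good = area2 > 1e-12
    if not good.all():
        warnings.warn(f"skipping {int((~good).sum())} degenerate triangle(s)")
    lap = np.zeros_like(v)
    area_mixed = np.zeros(n)
    sq = [np.einsum("ij,ij->i", ek, ek) for ek in e]  # squared edge lengths
    for k in range(3):
        i = f[:, k]
        j1 = f[:, (k + 1) % 3]
        j2 = f[:, (k + 2) % 3]
        # cotangent at vertex k of each face
        dot = np.einsum("ij,ij->i", v[j1] - v[i], v[j2] - v[i])
        cot = np.where(good, dot / np.maximum(area2, 1e-300), 0.0)
        # cot(k) weights the edge opposite k, i.e. (j1, j2)
        w = 0.5 * cot
        np.add.at(lap, j1, w[:, None] * (v[j2] - v[j1]))
        np.add.at(lap, j2, w[:, None] * (v[j1] - v[j2]))
    # mixed Voronoi areas
    obtuse_at = [np.einsum("ij,ij->i", e[(k + 1) % 3], e[(k + 2) % 3]) > 0 for k in range(3)]
    # note: interior angle at k is obtuse iff edges from k have negative dot;
    # with e[k] the edge *opposite* k, angle at k obtuse ⇔ dot(e_{k+1}, e_{k+2}) > 0
    any_obtuse = obtuse_at[0] | obtuse_at[1] | obtuse_at[2]
    face_area = 0.5 * area2
    for k in range(3):
        i = f[:, k]
        # Voronoi contribution for non-obtuse faces
        cot1 = np.einsum("ij,ij->i", v[f[:, (k + 1) % 3]] - v[f[:, (k + 2) % 3]], v[i] - v[f[:, (k + 2) % 3]])
        cot1 = cot1 / np.maximum(area2, 1e-300)  # cot at k+2, weights edge (i, k+1)
        cot2 = np.einsum("ij,ij->i", v[f[:, (k + 2) % 3]] - v[f[:, (k + 1) % 3]], v[i] - v[f[:, (k + 1) % 3]])
        cot2 = cot2 / np.maximum(area2, 1e-300)  # cot at k+1, weights edge (i, k+2)
        # sq[m] is the squared length of the edge opposite vertex m: edge
        # (i, j1) is opposite j2 and is weighted by the cotangent at j2
        voronoi = 0.125 * (cot1 * sq[(k + 2) % 3] + cot2 * sq[(k + 1) % 3])
        fallback = np.where(obtuse_at[k], 0.5 * face_area, 0.25 * face_area)
        contrib = np.where(good, np.where(any_obtuse, fallback, voronoi), 0.0)
        np.add.at(area_mixed, i, contrib)
    normals = vertex_normals(mesh)
    ok = (area_mixed > 1e-12) & ~mesh.boundary_vertices()
    lap = lap / np.maximum(area_mixed, 1e-300)[:, None]
    h = -0.5 * np.einsum("ij,ij->i", lap, normals)
    h = np.where(ok, h, np.nan)
    return h, ok


def out_of_plane_deformation(m0: TriMeshFrame, m1: TriMeshFrame, dt: float | None = None) -> DeformationFrame:
    """Covariant out-of-plane deformation d = 2·H·v_n between two frames.

    ``v_n`` is the forward-difference vertex velocity projected on the
    area-weighted outward normal of the first frame; ``H`` is the discrete
    mean curvature of the first frame.  Requires material vertex
    correspondence between the frames.
    """
    if len(m0.vertices) != len(m1.vertices):
        raise ValueError("frames must have material vertex correspondence")
    if dt is None:
        dt = m1.time - m0.time
    if dt <= 0:
        raise ValueError("dt must be positive")
    normals = vertex_normals(m0)
    v_n = np.einsum("ij,ij->i", (m1.vertices - m0.vertices) / dt, normals)
    h, ok = mean_curvature(m0)
    d = np.where(ok, 2.0 * h * v_n, np.nan)
    return DeformationFrame(h, np.where(ok, v_n, np.nan), d, ok, m0.time)


def lagrangian_autocorr(frames: list) -> SimilarityMatrix:
    """Tissue-frame (Lagrangian) correlation matrix of deformation fields.

    Entry (i, j) is the Pearson correlation over jointly valid vertices of
    ``d_i`` against ``d_j``; constant fields produce missing entries.
    """
    n = len(frames)
    if n < 2:
        raise ValueError("need at least 2 deformation frames")
    m = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i, n):
            ok = frames[i].valid & frames[j].valid
            if ok.sum() < 3:
                continue
            a, b = frames[i].d[ok], frames[j].d[ok]
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                continue
            m[i, j] = m[j, i] = _pearson(a, b)
    times = np.array([f.time for f in frames])
    return SimilarityMatrix(m, times, times, "lagrangian_2Hvn")
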