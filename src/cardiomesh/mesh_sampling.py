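"""Multi-resolution mesh hierarchy for hierarchical graph-convolutional models.

Downsampling is Garland-Heckbert quadric-error edge collapse restricted to
*vertex-subset* collapses: a removed vertex merges into one of its neighbours
at that neighbour's original position, so every coarse vertex is an original
fine vertex.  Removed vertices are remembered through the barycentric
coordinates of their projection onto the nearest coarse triangle; the sparse
up-transform reinserts them in the upsampling step, which is exact for linear
(affine) vertex fields on planar regions.
"""

from __future__ import annotations

import hashlib
import heapq
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.io
import scipy.sparse as sparse

from .errors import ConfigurationError
from .graph_conv import normalized_laplacian
from .mesh_core import Mesh, point_triangle_distances, read_mesh, write_mesh


@dataclass
class SamplingHierarchy:
    """Meshes from full resolution (level 0) to coarsest, with transforms.

    ``down_transforms[i]`` maps level-i vertex fields to level i+1 (vertex
    selection); ``up_transforms[i]`` maps level i+1 back to level i with at
    most three non-negative barycentric weights per row, each row summing
    to 1.  ``laplacians[i]`` is the symmetric normalized graph Laplacian of
    level i's edge graph.
    """

    levels: list[Mesh]
    down_transforms: list[sparse.csr_matrix]
    up_transforms: list[sparse.csr_matrix]
    laplacians: list[sparse.csr_matrix]

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def level_sizes(self) -> list[int]:
        return [m.n_vertices for m in self.levels]

    def content_hash(self) -> str:
        """SHA-256 over level geometry and transform triplets (reload check)."""
        h = hashlib.sha256()
        for m in self.levels:
            h.update(np.ascontiguousarray(m.vertices).tobytes())
            h.update(np.ascontiguousarray(m.faces).tobytes())
        for mats in (self.down_transforms, self.up_transforms):
            for mat in mats:
                coo = mat.tocoo()
                h.update(coo.row.astype(np.int64).tobytes())
                h.update(coo.col.astype(np.int64).tobytes())
                h.update(coo.data.astype(np.float64).tobytes())
        return h.hexdigest()

    def save(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for i, mesh in enumerate(self.levels):
            write_mesh(mesh, out / f"level_{i}.ply")
            # PLY stores float32; keep a full-precision copy so reload is
            # bit-identical (MatrixMarket dense array, text).
            scipy.io.mmwrite(str(out / f"level_{i}_vertices.mtx"), mesh.vertices, precision=17)
        for name, mats in (
            ("down", self.down_transforms),
            ("up", self.up_transforms),
            ("laplacian", self.laplacians),
        ):
            for i, mat in enumerate(mats):
                scipy.io.mmwrite(str(out / f"{name}_{i}.mtx"), mat.tocoo(), precision=17)
        meta = {
            "n_levels": self.n_levels,
            "level_sizes": self.level_sizes(),
            "content_hash": self.content_hash(),
            "phases": [m.phase for m in self.levels],
        }
        (out / "meta.json").write_text(json.dumps(meta, indent=2))
        return out

    @classmethod
    def load(cls, in_dir: str | Path) -> "SamplingHierarchy":
        d = Path(in_dir)
        meta = json.loads((d / "meta.json").read_text())
        n = meta["n_levels"]
        levels = []
        for i in range(n):
            mesh = read_mesh(d / f"level_{i}.ply", phase=meta["phases"][i])
            mesh.vertices = np.asarray(scipy.io.mmread(str(d / f"level_{i}_vertices.mtx")), dtype=np.float64)
            levels.append(mesh)
        down = [sparse.csr_matrix(scipy.io.mmread(str(d / f"down_{i}.mtx"))) for i in range(n - 1)]
        up = [sparse.csr_matrix(scipy.io.mmread(str(d / f"up_{i}.mtx"))) for i in range(n - 1)]
        lap = [sparse.csr_matrix(scipy.io.mmread(str(d / f"laplacian_{i}.mtx"))) for i in range(n)]
        hier = cls(levels, down, up, lap)
        if hier.content_hash() != meta["content_hash"]:
            raise ConfigurationError(f"hierarchy in {d} does not match its stored content hash")
        return hier


# ---------------------------------------------------------------------------
# Quadric-error decimation (vertex-subset edge collapse)
# ---------------------------------------------------------------------------

def _face_quadric(v0: np.ndarray, v1: np.ndarray, v2: np.ndarray) -> np.ndarray:
    """Area-weighted fundamental quadric of a triangle's supporting plane."""
    n = np.cross(v1 - v0, v2 - v0)
    area2 = np.linalg.norm(n)
    if area2 < 1e-300:
        return np.zeros((4, 4))
    n_unit = n / area2
    d = -np.dot(n_unit, v0)
    p = np.append(n_unit, d)
    return 0.5 * area2 * np.outer(p, p)


def _boundary_quadric(v0: np.ndarray, v1: np.ndarray, face_normal: np.ndarray, weight: float) -> np.ndarray:
    """Constraint quadric of a plane through a boundary edge, perpendicular to its face."""
    e = v1 - v0
    n = np.cross(e, face_normal)
    norm = np.linalg.norm(n)
    if norm < 1e-300:
        return np.zeros((4, 4))
    n /= norm
    d = -np.dot(n, v0)
    p = np.append(n, d)
    return weight * np.outer(p, p)


def _quadric_cost(Q: np.ndarray, v: np.ndarray) -> float:
    h = np.append(v, 1.0)
    return float(h @ Q @ h)


def decimate(mesh: Mesh, target_fraction: float, boundary_weight: float = 100.0):
    """Quadric edge collapse down to ``ceil(V * target_fraction)`` vertices.

    Collapses merge one endpoint into the other at the kept endpoint's
    original position, chosen greedily by minimal quadric error with a
    face-flip guard; ties break on (error, removed index, kept index) for
    cross-platform determinism.  Returns ``(coarse_mesh, kept_indices)``
    where ``kept_indices`` maps coarse vertex order to fine vertex indices.
    """
    if not 0.0 < target_fraction < 1.0:
        raise ConfigurationError(f"target_fraction must be in (0, 1), got {target_fraction}")
    mesh.validate()
    V = mesh.n_vertices
    target = int(np.ceil(V * target_fraction))
    verts = mesh.vertices

    quadrics = [np.zeros((4, 4)) for _ in range(V)]
    face_set: set[tuple[int, int, int]] = set()
    vertex_faces: list[set[tuple[int, int, int]]] = [set() for _ in range(V)]
    edge_count: dict[tuple[int, int], int] = {}
    face_normals: dict[tuple[int, int, int], np.ndarray] = {}
    for f in mesh.faces:
        key = tuple(int(x) for x in f)
        face_set.add(key)
        q = _face_quadric(verts[f[0]], verts[f[1]], verts[f[2]])
        n = np.cross(verts[f[1]] - verts[f[0]], verts[f[2]] - verts[f[0]])
        face_normals[key] = n
        for v in key:
            quadrics[v] = quadrics[v] + q
            vertex_faces[v].add(key)
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            e = (int(min(a, b)), int(max(a, b)))
            edge_count[e] = edge_count.get(e, 0) + 1
    # Boundary penalties keep open rims from collapsing inwards.
    for (a, b), cnt in edge_count.items():
        if cnt == 1:
            face = next(k for k in vertex_faces[a] if b in k)
            bq = _boundary_quadric(verts[a], verts[b], face_normals[face], boundary_weight)
            quadrics[a] = quadrics[a] + bq
            quadrics[b] = quadrics[b] + bq

    alive = np.ones(V, dtype=bool)
    n_alive = V
    version = np.zeros(V, dtype=np.int64)

    def neighbors(v: int) -> set[int]:
        out: set[int] = set()
        for f in vertex_faces[v]:
            out.update(f)
        out.discard(v)
        return out

    heap: list[tuple[float, int, int, int, int]] = []

    def push_candidates(v: int) -> None:
        for u in neighbors(v):
            for rem, keep in ((v, u), (u, v)):
                cost = _quadric_cost(quadrics[rem] + quadrics[keep], verts[keep])
                heapq.heappush(heap, (cost, rem, keep, int(version[rem]), int(version[keep])))

    for v in range(V):
        for u in neighbors(v):
            if u > v:
                for rem, keep in ((v, u), (u, v)):
                    cost = _quadric_cost(quadrics[rem] + quadrics[keep], verts[keep])
                    heapq.heappush(heap, (cost, rem, keep, 0, 0))

    def collapse_ok(rem: int, keep: int) -> bool:
        """Reject collapses that flip or degenerate any surviving face."""
        for f in vertex_faces[rem]:
            if keep in f:
                continue  # face vanishes
            new = tuple(keep if x == rem else x for x in f)
            if len(set(new)) < 3:
                return False
            n_old = face_normals[f]
            n_new = np.cross(verts[new[1]] - verts[new[0]], verts[new[2]] - verts[new[0]])
            norm_old = np.linalg.norm(n_old)
            norm_new = np.linalg.norm(n_new)
            if norm_new < 1e-12 * max(norm_old, 1.0):
                return False
            if norm_old > 1e-300 and np.dot(n_old, n_new) < 0:
                return False
        return True

    while n_alive > target and heap:
        cost, rem, keep, vrem, vkeep = heapq.heappop(heap)
        if not (alive[rem] and alive[keep]):
            continue
        if vrem != version[rem] or vkeep != version[keep]:
            continue  # stale entry
        if keep not in neighbors(rem):
            continue
        if not collapse_ok(rem, keep):
            # Drop the candidate; it is re-proposed automatically if a later
            # collapse changes the local topology (push_candidates on keep).
            continue
        # Perform collapse rem -> keep.
        alive[rem] = False
        n_alive -= 1
        quadrics[keep] = quadrics[keep] + quadrics[rem]
        for f in list(vertex_faces[rem]):
            for v in f:
                vertex_faces[v].discard(f)
            face_set.discard(f)
            face_normals.pop(f, None)
            new = tuple(keep if x == rem else x for x in f)
            if len(set(new)) < 3 or new in face_set:
                continue
            face_set.add(new)
            face_normals[new] = np.cross(verts[new[1]] - verts[new[0]], verts[new[2]] - verts[new[0]])
            for v in new:
                vertex_faces[v].add(new)
        version[rem] += 1
        version[keep] += 1
        push_candidates(keep)

    if n_alive > target:
        warnings.warn(f"collapse queue exhausted at {n_alive} vertices (target {target})")

    kept = np.flatnonzero(alive)
    remap = -np.ones(V, dtype=np.int64)
    remap[kept] = np.arange(len(kept))
    coarse_faces = np.array(sorted(tuple(int(remap[v]) for v in f) for f in face_set), dtype=np.int64)
    labels = None if mesh.vertex_labels is None else mesh.vertex_labels[kept]
    coarse = Mesh(verts[kept].copy(), coarse_faces, labels, mesh.phase)
    return coarse, kept


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def build_down_transform(n_fine: int, kept: np.ndarray) -> sparse.csr_matrix:
    """Vertex-selection matrix: row r picks fine vertex ``kept[r]``."""
    n_coarse = len(kept)
    return sparse.csr_matrix(
        (np.ones(n_coarse), (np.arange(n_coarse), kept)), shape=(n_coarse, n_fine)
    )


def build_up_transform(fine: Mesh, coarse: Mesh, kept: np.ndarray) -> sparse.csr_matrix:
    """Barycentric reinsertion matrix mapping coarse fields back to fine vertices.

    Kept vertices map to themselves with weight 1; each removed vertex gets
    the barycentric weights of its closest-point projection onto the nearest
    coarse triangle (clamped to the triangle, so rows are convex
    combinations).
    """
    n_fine, n_coarse = fine.n_vertices, coarse.n_vertices
    rows, cols, vals = [], [], []
    coarse_of_fine = -np.ones(n_fine, dtype=np.int64)
    coarse_of_fine[kept] = np.arange(n_coarse)

    removed = np.flatnonzero(coarse_of_fine < 0)
    for r in kept:
        rows.append(r)
        cols.append(coarse_of_fine[r])
        vals.append(1.0)

    if len(removed):
        tris = coarse.triangle_coordinates()
        sq, S, T = point_triangle_distances_with_params(fine.vertices[removed], tris)
        best = np.argmin(sq, axis=1)
        for i, v in enumerate(removed):
            t_idx = best[i]
            s, t = S[i, t_idx], T[i, t_idx]
            w = np.array([1.0 - s - t, s, t])
            w = np.clip(w, 0.0, 1.0)
            w /= w.sum()
            for corner, weight in zip(coarse.faces[t_idx], w):
                if weight > 0:
                    rows.append(v)
                    cols.append(corner)
                    vals.append(float(weight))
    return sparse.csr_matrix((vals, (rows, cols)), shape=(n_fine, n_coarse))


def point_triangle_distances_with_params(points: np.ndarray, triangles: np.ndarray):
    """Squared point-triangle distances plus the clamped barycentric
    parameters (s, t) of each closest point, shapes (N, M) each."""
    points = np.asarray(points, dtype=np.float64)
    triangles = np.asarray(triangles, dtype=np.float64)
    B = triangles[:, 0]
    E0 = triangles[:, 1] - B
    E1 = triangles[:, 2] - B
    a = np.einsum("ij,ij->i", E0, E0)
    b = np.einsum("ij,ij->i", E0, E1)
    c = np.einsum("ij,ij->i", E1, E1)
    D = B[None, :, :] - points[:, None, :]
    d = np.einsum("nmj,mj->nm", D, E0)
    e = np.einsum("nmj,mj->nm", D, E1)
    f = np.einsum("nmj,nmj->nm", D, D)

    det = np.maximum(a * c - b * b, 1e-300)
    s = b * e - c * d
    t = b * d - a * e
    denom = np.maximum(a - 2.0 * b + c, 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        s0 = s / det
        t0 = t / det
        t_edge0 = np.clip(-e / np.maximum(c, 1e-300), 0.0, 1.0)
        s_edge1 = np.clip(-d / np.maximum(a, 1e-300), 0.0, 1.0)
        s_diag = np.clip((c + e - b - d) / denom, 0.0, 1.0)
        T6 = np.clip((a + d - b - e) / denom, 0.0, 1.0)

    inside = s + t <= det
    reg0 = inside & (s >= 0) & (t >= 0)
    reg3 = inside & (s < 0) & (t >= 0)
    reg5 = inside & (s >= 0) & (t < 0)
    reg4 = inside & (s < 0) & (t < 0)
    out = ~inside
    reg2 = out & (s < 0)
    reg6 = out & (s >= 0) & (t < 0)
    reg1 = out & (s >= 0) & (t >= 0)

    S = np.where(reg0, s0, 0.0)
    T = np.where(reg0, t0, 0.0)
    S = np.where(reg3, 0.0, S)
    T = np.where(reg3, t_edge0, T)
    S = np.where(reg5, s_edge1, S)
    T = np.where(reg5, 0.0, T)
    r4a = reg4 & (d < 0)
    r4b = reg4 & ~(d < 0)
    S = np.where(r4a, s_edge1, S)
    T = np.where(r4a, 0.0, T)
    S = np.where(r4b, 0.0, S)
    T = np.where(r4b, t_edge0, T)
    S = np.where(reg1, s_diag, S)
    T = np.where(reg1, 1.0 - s_diag, T)
    use_diag2 = reg2 & ((c + e) > (b + d))
    S = np.where(use_diag2, s_diag, S)
    T = np.where(use_diag2, 1.0 - s_diag, T)
    rest2 = reg2 & ~use_diag2
    S = np.where(rest2, 0.0, S)
    T = np.where(rest2, t_edge0, T)
    use_diag6 = reg6 & ((a + d) > (b + e))
    S = np.where(use_diag6, 1.0 - T6, S)
    T = np.where(use_diag6, T6, T)
    rest6 = reg6 & ~use_diag6
    S = np.where(rest6, s_edge1, S)
    T = np.where(rest6, 0.0, T)

    sq = a * S * S + 2.0 * b * S * T + c * T * T + 2.0 * d * S + 2.0 * e * T + f
    return np.maximum(sq, 0.0), S, T


# ---------------------------------------------------------------------------
# Hierarchy
# ---------------------------------------------------------------------------

def build_hierarchy(template: Mesh, n_levels: int = 4, factor: float = 4.0) -> SamplingHierarchy:
    """Chain of quadric decimations (default 4 levels at factor 4: 2450 ->
    613 -> 154 -> 39) with down/up transforms and per-level Laplacians."""
    if n_levels < 1:
        raise ConfigurationError("n_levels must be >= 1")
    if factor <= 1:
        raise ConfigurationError("factor must be > 1")
    levels = [template]
    down, up = [], []
    for _ in range(n_levels - 1):
        fine = levels[-1]
        if int(np.ceil(fine.n_vertices / factor)) < 4:
            raise ConfigurationError(
                f"decimating {fine.n_vertices} vertices by {factor} drops below 4; use fewer levels"
            )
        coarse, kept = decimate(fine, 1.0 / factor)
        levels.append(coarse)
        down.append(build_down_transform(fine.n_vertices, kept))
        up.append(build_up_transform(fine, coarse, kept))
    laplacians = [normalized_laplacian(m.edges(), m.n_vertices) for m in levels]
    return SamplingHierarchy(levels, down, up, laplacians)
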