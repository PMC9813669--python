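"""Mesh data model, I/O, correspondence checks, and geometric/clinical metrics.

Meshes are triangular surfaces of the left ventricle (LV) with vertex
coordinates in millimetres.  All subjects in a corresponded dataset share one
face array, so vertex ``i`` refers to the same anatomical location in every
subject.  Per-vertex anatomical labels distinguish the endocardial (inner)
surface, the epicardial (outer) surface, and the basal rim band joining them
at the ventricular base.

Distance metrics follow the surface-distance convention: the distance from a
point to the other mesh is the Euclidean distance to the closest point on any
of its triangles, not to the closest vertex.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .errors import (
    DataLeakageError,
    EmptyInputError,
    InvalidAnatomyError,
    MeshParseError,
    TopologyError,
    UnsupportedTopologyError,
)

# Per-vertex anatomical label codes.
ENDOCARDIAL = 0
EPICARDIAL = 1
BASAL_RIM = 2

LABEL_NAMES = {ENDOCARDIAL: "endocardial", EPICARDIAL: "epicardial", BASAL_RIM: "basal_rim"}
LABEL_CODES = {v: k for k, v in LABEL_NAMES.items()}

#: Myocardial tissue density in g/mL used for LV mass.
MYOCARDIAL_DENSITY_G_PER_ML = 1.05

#: Vertex count of the full-resolution corresponded LV template.
TEMPLATE_VERTEX_COUNT = 2450

_SUPPORTED_FORMATS = ("ply", "obj", "off")


@dataclass
class Mesh:
    """A triangular surface mesh with optional anatomical labels.

    Parameters
    ----------
    vertices : (V, 3) float array, mm
    faces : (F, 3) int array of vertex indices
    vertex_labels : (V,) int array with codes in {ENDOCARDIAL, EPICARDIAL,
        BASAL_RIM}, or None when the mesh carries no anatomical labels
    phase : "ED", "ES" or "unspecified"
    """

    vertices: np.ndarray
    faces: np.ndarray
    vertex_labels: np.ndarray | None = None
    phase: str = "unspecified"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise UnsupportedTopologyError(f"vertices must be (V, 3), got {self.vertices.shape}")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise UnsupportedTopologyError(f"faces must be (F, 3) triangles, got {self.faces.shape}")
        if self.vertex_labels is not None:
            self.vertex_labels = np.asarray(self.vertex_labels, dtype=np.int64)
            if self.vertex_labels.shape != (len(self.vertices),):
                raise UnsupportedTopologyError("vertex_labels must have one entry per vertex")
        if self.phase not in ("ED", "ES", "unspecified"):
            raise ValueError(f"phase must be ED/ES/unspecified, got {self.phase!r}")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def validate(self) -> None:
        """Raise if face indices are out of range or faces are degenerate."""
        if self.n_vertices == 0 or self.n_faces == 0:
            raise EmptyInputError("mesh has no vertices or no faces")
        if self.faces.min() < 0 or self.faces.max() >= self.n_vertices:
            raise UnsupportedTopologyError("face index out of range")
        f = self.faces
        degen = (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])
        if degen.any():
            raise UnsupportedTopologyError(f"{int(degen.sum())} degenerate faces (repeated vertex index)")

    def edges(self) -> np.ndarray:
        """Unique undirected edges as a (E, 2) sorted-index array."""
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def copy(self) -> "Mesh":
        return Mesh(
            self.vertices.copy(),
            self.faces.copy(),
            None if self.vertex_labels is None else self.vertex_labels.copy(),
            self.phase,
        )

    def with_vertices(self, vertices: np.ndarray) -> "Mesh":
        """Same connectivity and labels, new coordinates."""
        return replace(self, vertices=np.asarray(vertices, dtype=np.float64))

    def triangle_coordinates(self) -> np.ndarray:
        """(F, 3, 3) array of triangle corner coordinates."""
        return self.vertices[self.faces]


@dataclass
class MeshDataset:
    """An ordered, corresponded collection of meshes (one per subject)."""

    meshes: list[Mesh]
    subject_ids: list[str]
    labels: np.ndarray | None = None  # binary outcome per subject
    split: np.ndarray | None = None  # "train"/"val"/"test" per subject

    def __post_init__(self) -> None:
        if len(self.meshes) != len(self.subject_ids):
            raise ValueError("meshes and subject_ids must have equal length")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.split is not None:
            self.split = np.asarray(self.split, dtype=object)

    def __len__(self) -> int:
        return len(self.meshes)

    def __iter__(self):
        return iter(self.meshes)

    def subset(self, mask: np.ndarray) -> "MeshDataset":
        idx = np.flatnonzero(mask)
        return MeshDataset(
            [self.meshes[i] for i in idx],
            [self.subject_ids[i] for i in idx],
            None if self.labels is None else self.labels[idx],
            None if self.split is None else self.split[idx],
        )

    def split_subset(self, name: str) -> "MeshDataset":
        if self.split is None:
            raise ValueError("dataset has no split assignment")
        return self.subset(self.split == name)

    def coordinates(self) -> np.ndarray:
        """(n, V, 3) stacked vertex coordinates."""
        return np.stack([m.vertices for m in self.meshes])


@dataclass
class CorrespondenceReport:
    passed: bool
    n_meshes: int
    failures: list[tuple[str, str]] = field(default_factory=list)

    def __str__(self) -> str:
        if self.passed:
            return f"correspondence OK across {self.n_meshes} meshes"
        lines = [f"correspondence FAILED ({len(self.failures)} meshes):"]
        lines += [f"  {sid}: {reason}" for sid, reason in self.failures]
        return "\n".join(lines)


def validate_correspondence(dataset: MeshDataset) -> CorrespondenceReport:
    """Check that every mesh shares the first mesh's vertex count and faces.

    The check is order-sensitive: reordered faces break the vertex-wise
    training objective even though the surface is geometrically identical.
    """
    if len(dataset) == 0:
        raise EmptyInputError("empty dataset")
    ref = dataset.meshes[0]
    failures: list[tuple[str, str]] = []
    for mesh, sid in zip(dataset.meshes, dataset.subject_ids):
        if mesh.n_vertices != ref.n_vertices:
            failures.append((sid, f"vertex count {mesh.n_vertices} != {ref.n_vertices}"))
        elif mesh.faces.shape != ref.faces.shape or not np.array_equal(mesh.faces, ref.faces):
            failures.append((sid, "face array differs from reference"))
    return CorrespondenceReport(passed=not failures, n_meshes=len(dataset), failures=failures)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_mesh(path: str | Path, file_format: str | None = None, phase: str = "unspecified") -> Mesh:
    """Read a triangular mesh from PLY/OBJ/OFF, with an optional label side-car.

    Labels are looked up in ``<stem>.labels.csv`` next to the mesh file
    (columns ``vertex_index,label``); absent side-car means unlabeled mesh.
    Vertex order and coordinates are preserved as stored.
    """
    path = Path(path)
    if not path.exists():
        raise MeshParseError(f"no such file: {path}")
    fmt = (file_format or path.suffix.lstrip(".")).lower()
    if fmt not in _SUPPORTED_FORMATS:
        raise MeshParseError(f"unsupported format {fmt!r}; expected one of {_SUPPORTED_FORMATS}")
    _reject_non_triangular(path, fmt)
    try:
        loaded = trimesh.load(str(path), file_type=fmt, process=False, maintain_order=True)
    except Exception as exc:  # trimesh raises assorted exception types
        raise MeshParseError(f"cannot parse {path} as {fmt}: {exc}") from exc
    if not isinstance(loaded, trimesh.Trimesh):
        raise UnsupportedTopologyError(f"{path}: not a single triangular surface (got {type(loaded).__name__})")
    faces = np.asarray(loaded.faces)
    if faces.size and faces.shape[1] != 3:
        raise UnsupportedTopologyError(f"{path}: non-triangular faces")
    labels = None
    sidecar = path.with_suffix(".labels.csv")
    if sidecar.exists():
        labels = _read_label_sidecar(sidecar, len(loaded.vertices))
    mesh = Mesh(np.asarray(loaded.vertices, dtype=np.float64), faces, labels, phase)
    mesh.validate()
    return mesh


def write_mesh(mesh: Mesh, path: str | Path, encoding: str = "binary") -> Path:
    """Write a mesh (format from the extension); labels go to a CSV side-car."""
    path = Path(path)
    fmt = path.suffix.lstrip(".").lower()
    if fmt not in _SUPPORTED_FORMATS:
        raise MeshParseError(f"unsupported output format {fmt!r}")
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    if fmt == "ply":
        path.write_bytes(tm.export(file_type="ply", encoding=encoding))
    else:
        tm.export(str(path))
    if mesh.vertex_labels is not None:
        with open(path.with_suffix(".labels.csv"), "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["vertex_index", "label"])
            for i, code in enumerate(mesh.vertex_labels):
                w.writerow([i, LABEL_NAMES[int(code)]])
    return path


def _reject_non_triangular(path: Path, fmt: str) -> None:
    """Fail fast on polygonal faces in ASCII OFF/OBJ before trimesh
    silently triangulates them (ASCII PLY declares its face list sizes in
    the header, which trimesh handles; quads there are caught below too)."""
    if fmt == "obj":
        for line_no, line in enumerate(path.read_text(errors="replace").splitlines(), 1):
            if line.startswith("f ") and len(line.split()) - 1 != 3:
                raise UnsupportedTopologyError(f"{path}:{line_no}: non-triangular face in OBJ")
    elif fmt == "off":
        lines = [ln.split("#")[0].strip() for ln in path.read_text(errors="replace").splitlines()]
        lines = [ln for ln in lines if ln]
        if not lines or not lines[0].upper().startswith("OFF"):
            return  # let trimesh report the parse failure
        header = lines[1].split() if lines[0].upper() == "OFF" else lines[0].split()[1:]
        body = lines[2:] if lines[0].upper() == "OFF" else lines[1:]
        try:
            n_v, n_f = int(header[0]), int(header[1])
        except (IndexError, ValueError):
            return
        for offset, ln in enumerate(body[n_v : n_v + n_f]):
            if ln.split() and int(ln.split()[0]) != 3:
                raise UnsupportedTopologyError(f"{path}: face record {offset}: non-triangular face in OFF")


def _read_label_sidecar(path: Path, n_vertices: int) -> np.ndarray:
    labels = np.full(n_vertices, -1, dtype=np.int64)
    with open(path, newline="") as fh:
        for rec_no, row in enumerate(csv.DictReader(fh)):
            try:
                idx = int(row["vertex_index"])
                labels[idx] = LABEL_CODES[row["label"]]
            except (KeyError, ValueError, IndexError) as exc:
                raise MeshParseError(f"{path}: bad label record {rec_no}: {row}") from exc
    if (labels < 0).any():
        raise MeshParseError(f"{path}: labels missing for {(labels < 0).sum()} vertices")
    return labels


# ---------------------------------------------------------------------------
# Point-to-surface distances (MSD / Hausdorff)
# ---------------------------------------------------------------------------

def point_triangle_distances(points: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Squared distances from each point to each triangle, shape (N, M).

    Vectorised closest-point-on-triangle computation (Eberly's region-based
    algorithm) over all point/triangle pairs.
    """
    points = np.asarray(points, dtype=np.float64)
    triangles = np.asarray(triangles, dtype=np.float64)
    B = triangles[:, 0]  # (M, 3)
    E0 = triangles[:, 1] - B
    E1 = triangles[:, 2] - B
    a = np.einsum("ij,ij->i", E0, E0)
    b = np.einsum("ij,ij->i", E0, E1)
    c = np.einsum("ij,ij->i", E1, E1)
    D = B[None, :, :] - points[:, None, :]  # (N, M, 3)
    d = np.einsum("nmj,mj->nm", D, E0)
    e = np.einsum("nmj,mj->nm", D, E1)
    f = np.einsum("nmj,nmj->nm", D, D)

    det = np.maximum(a * c - b * b, 1e-300)
    s = b * e - c * d
    t = b * d - a * e

    denom = np.maximum(a - 2.0 * b + c, 1e-300)

    with np.errstate(divide="ignore", invalid="ignore"):
        # Region 0: interior of the triangle.
        s0 = s / det
        t0 = t / det
        # Edge/vertex regions, each with clamped parameters.
        t_edge0 = np.clip(-e / np.maximum(c, 1e-300), 0.0, 1.0)  # s = 0 edge
        s_edge1 = np.clip(-d / np.maximum(a, 1e-300), 0.0, 1.0)  # t = 0 edge
        s_diag = np.clip((c + e - b - d) / denom, 0.0, 1.0)  # s + t = 1 edge

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
    # region 3: closest on edge s=0
    S = np.where(reg3, 0.0, S)
    T = np.where(reg3, t_edge0, T)
    # region 5: closest on edge t=0
    S = np.where(reg5, s_edge1, S)
    T = np.where(reg5, 0.0, T)
    # region 4: nearest of the two edges through the base vertex
    r4a = reg4 & (d < 0)
    r4b = reg4 & ~(d < 0)
    S = np.where(r4a, s_edge1, S)
    T = np.where(r4a, 0.0, T)
    S = np.where(r4b, 0.0, S)
    T = np.where(r4b, t_edge0, T)
    # region 1: diagonal edge
    S = np.where(reg1, s_diag, S)
    T = np.where(reg1, 1.0 - s_diag, T)
    # region 2: diagonal edge or edge s=0
    use_diag2 = reg2 & ((c + e) > (b + d))
    S = np.where(use_diag2, s_diag, S)
    T = np.where(use_diag2, 1.0 - s_diag, T)
    rest2 = reg2 & ~use_diag2
    S = np.where(rest2, 0.0, S)
    T = np.where(rest2, t_edge0, T)
    # region 6: diagonal edge or edge t=0
    use_diag6 = reg6 & ((a + d) > (b + e))
    T6 = np.clip((a + d - b - e) / denom, 0.0, 1.0)
    S = np.where(use_diag6, 1.0 - T6, S)
    T = np.where(use_diag6, T6, T)
    rest6 = reg6 & ~use_diag6
    S = np.where(rest6, s_edge1, S)
    T = np.where(rest6, 0.0, T)

    sq = a * S * S + 2.0 * b * S * T + c * T * T + 2.0 * d * S + 2.0 * e * T + f
    return np.maximum(sq, 0.0)


def directed_surface_distance(points: np.ndarray, target: Mesh) -> np.ndarray:
    """Distance from each query point to the closest point on ``target``'s surface.

    A vertex KD-tree gives an upper bound per query point; triangles whose
    bounding sphere cannot beat that bound are pruned before the exact
    point-to-triangle evaluation.
    """
    points = np.asarray(points, dtype=np.float64)
    tris = target.triangle_coordinates()
    n_tris = len(tris)
    if n_tris == 0:
        raise EmptyInputError("target mesh has no faces")
    if n_tris <= 256 or len(points) <= 64:
        return np.sqrt(point_triangle_distances(points, tris).min(axis=1))

    vert_tree = cKDTree(target.vertices)
    upper, _ = vert_tree.query(points)
    centroids = tris.mean(axis=1)
    radius = np.sqrt(((tris - centroids[:, None, :]) ** 2).sum(axis=2)).max(axis=1)
    cent_tree = cKDTree(centroids)
    r_max = radius.max()
    # Any triangle containing a closer point than `upper` has its centroid
    # within upper + r_max of the query point.
    candidates = cent_tree.query_ball_point(points, upper + r_max + 1e-12)
    out = np.empty(len(points))
    for i, cand in enumerate(candidates):
        cand = np.asarray(cand, dtype=np.int64)
        sq = point_triangle_distances(points[i : i + 1], tris[cand])
        out[i] = np.sqrt(sq.min())
    return out


def mean_surface_distance(x: Mesh, y: Mesh) -> float:
    """Symmetric mean surface distance in mm.

    Average of the two directed mean vertex-to-surface distances:
    ``(mean_i d(x_i, Y) + mean_j d(y_j, X)) / 2``.
    """
    _check_nonempty(x, y)
    dx = directed_surface_distance(x.vertices, y)
    dy = directed_surface_distance(y.vertices, x)
    return float(0.5 * (dx.mean() + dy.mean()))


def hausdorff_distance(x: Mesh, y: Mesh) -> float:
    """Symmetric Hausdorff distance in mm: worst-case vertex-to-surface distance."""
    _check_nonempty(x, y)
    dx = directed_surface_distance(x.vertices, y)
    dy = directed_surface_distance(y.vertices, x)
    return float(max(dx.max(), dy.max()))


def surface_distances(x: Mesh, y: Mesh) -> tuple[float, float]:
    """(MSD, HD) computed from one pass of directed distances."""
    _check_nonempty(x, y)
    dx = directed_surface_distance(x.vertices, y)
    dy = directed_surface_distance(y.vertices, x)
    return float(0.5 * (dx.mean() + dy.mean())), float(max(dx.max(), dy.max()))


def _check_nonempty(*meshes: Mesh) -> None:
    for m in meshes:
        if m.n_vertices == 0 or m.n_faces == 0:
            raise EmptyInputError("empty mesh in distance computation")


# ---------------------------------------------------------------------------
# Clinical metrics
# ---------------------------------------------------------------------------

def enclosed_volume(mesh: Mesh, surface: str = "endocardial", cap: str = "centroid_fan") -> float:
    """Volume (mL) enclosed by a labeled sub-surface, capped at the basal rim.

    The requested surface is the set of faces whose vertices all carry the
    surface label or the basal-rim label (with at least one surface-label
    vertex).  An open basal boundary is closed with a triangle fan to the
    boundary-loop centroid; the signed divergence-theorem volume of the closed
    surface is then returned in mL (1 mL = 1000 mm^3).  A mesh without labels
    is treated as one closed surface.
    """
    if cap != "centroid_fan":
        raise ValueError(f"unknown cap strategy {cap!r}")
    mesh.validate()
    if mesh.vertex_labels is None:
        faces = mesh.faces
    else:
        if surface not in ("endocardial", "epicardial"):
            raise ValueError(f"surface must be endocardial/epicardial, got {surface!r}")
        code = LABEL_CODES[surface]
        lab = mesh.vertex_labels[mesh.faces]
        allowed = (lab == code) | (lab == BASAL_RIM)
        faces = mesh.faces[allowed.all(axis=1) & (lab == code).any(axis=1)]
        if len(faces) == 0:
            raise TopologyError(f"no faces found for surface {surface!r}")

    tris = [mesh.vertices[faces]]
    boundary = _boundary_loop_edges(faces)
    if len(boundary):
        loop_vertices = _single_loop_or_raise(boundary)
        centroid = mesh.vertices[loop_vertices].mean(axis=0)
        # Cap triangle (b, a, centroid) reverses each directed boundary edge
        # (a, b), keeping the closed surface consistently oriented.
        cap_tris = np.stack(
            [mesh.vertices[boundary[:, 1]], mesh.vertices[boundary[:, 0]], np.broadcast_to(centroid, (len(boundary), 3))],
            axis=1,
        )
        tris.append(cap_tris)
    t = np.concatenate(tris)
    signed = np.einsum("ij,ij->i", t[:, 0], np.cross(t[:, 1], t[:, 2])).sum() / 6.0
    return abs(float(signed)) / 1000.0


def _boundary_loop_edges(faces: np.ndarray) -> np.ndarray:
    """Directed edges of ``faces`` that occur exactly once (boundary edges)."""
    directed = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    undirected = np.sort(directed, axis=1)
    _, inverse, counts = np.unique(undirected, axis=0, return_inverse=True, return_counts=True)
    return directed[counts[inverse] == 1]


def _single_loop_or_raise(boundary: np.ndarray) -> np.ndarray:
    """Vertices of the boundary, verifying it forms a single closed loop."""
    succ: dict[int, int] = {}
    for a, b in boundary:
        if int(a) in succ:
            raise TopologyError("non-manifold boundary: vertex with multiple outgoing boundary edges")
        succ[int(a)] = int(b)
    verts = set(succ)
    if set(succ.values()) != verts:
        raise TopologyError("boundary is not a closed loop")
    start = next(iter(succ))
    loop = [start]
    cur = succ[start]
    while cur != start:
        loop.append(cur)
        cur = succ[cur]
    if len(loop) != len(verts):
        raise TopologyError(f"boundary has multiple loops ({len(verts)} vertices, loop of {len(loop)})")
    return np.asarray(loop, dtype=np.int64)


def lv_mass(epicardial_volume_ml: float, endocardial_volume_ml: float) -> float:
    """LV myocardial mass in g: wall volume times 1.05 g/mL tissue density."""
    wall = epicardial_volume_ml - endocardial_volume_ml
    if wall < 0 or endocardial_volume_ml < 0:
        raise InvalidAnatomyError(
            f"negative wall volume: epi {epicardial_volume_ml} mL < endo {endocardial_volume_ml} mL"
        )
    return wall * MYOCARDIAL_DENSITY_G_PER_ML


def clinical_metrics(mesh: Mesh) -> dict[str, float]:
    """LV endocardial volume (mL) and LV mass (g) for one labeled mesh."""
    v_endo = enclosed_volume(mesh, "endocardial")
    v_epi = enclosed_volume(mesh, "epicardial")
    return {"lv_endo_volume_ml": v_endo, "lv_mass_g": lv_mass(v_epi, v_endo)}


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

@dataclass
class StandardizationStats:
    """Per-vertex-coordinate mean/SD computed on the training split only."""

    mean: np.ndarray  # (V, 3) mm
    sd: np.ndarray  # (V, 3) mm, strictly positive (floored)

    SD_FLOOR = 1e-8

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return (np.asarray(coords, dtype=np.float64) - self.mean) / self.sd

    def invert(self, standardized: np.ndarray) -> np.ndarray:
        return np.asarray(standardized, dtype=np.float64) * self.sd + self.mean


def fit_standardization(dataset: MeshDataset | Sequence[Mesh], split: str = "train") -> StandardizationStats:
    """Fit per-vertex-coordinate standardization on the training split.

    Requesting statistics from any other split raises ``DataLeakageError``:
    test/validation geometry must never inform the normalization.
    """
    if split != "train":
        raise DataLeakageError(f"standardization statistics must come from the train split, not {split!r}")
    if isinstance(dataset, MeshDataset):
        meshes: Iterable[Mesh] = dataset.split_subset("train").meshes if dataset.split is not None else dataset.meshes
    else:
        meshes = dataset
    coords = np.stack([m.vertices for m in meshes])
    if len(coords) < 2:
        raise EmptyInputError("need at least 2 training meshes to fit standardization")
    mean = coords.mean(axis=0)
    sd = coords.std(axis=0)
    sd = np.maximum(sd, StandardizationStats.SD_FLOOR)
    return StandardizationStats(mean=mean, sd=sd)
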