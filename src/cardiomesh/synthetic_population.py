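"""Synthetic corresponded LV mesh cohorts with controlled population variability.

The generator emulates the kind of data the shape model is built for: paired
end-diastolic (ED) / end-systolic (ES) left-ventricular surface meshes with
identical connectivity across subjects, population variation in a small set
of interpretable anatomical factors, short-axis slice-misalignment artifacts,
and a rare binary outcome (MACE) whose effect is planted in ES shape only.

The template is a truncated half-ellipsoid shell: an endocardial surface and
an epicardial surface (offset by the wall thickness), each built from an apex
pole plus latitude rings, joined at the base by a flat annulus whose vertices
carry the basal-rim label.  The default tessellation (50 latitude rings x 24
circumferential vertices per surface, one rim ring each) yields exactly 2,450
vertices.

Six generative factors drive inter-subject variability: overall size scale,
apex pointedness, basal tilt, longitudinal elongation, wall thickness, and
mid-cavity diameter.  ES meshes are derived from the same subject parameters
by cavity contraction (radial stronger than longitudinal) with wall
thickening, so every subject has a smaller, thicker-walled ES shape.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import mesh_core
from .errors import ConfigurationError
from .mesh_core import BASAL_RIM, ENDOCARDIAL, EPICARDIAL, Mesh, MeshDataset

# Documented default grid: apex + (n_rings + 1 rim) rings of n_circ vertices,
# per surface: 2 * (1 + 51 * 24) = 2450 vertices.
DEFAULT_N_RINGS = 50
DEFAULT_N_CIRC = 24

DEFAULT_ENDO_SEMI_AXES = (27.0, 27.0, 85.0)  # mm; ED cavity ~130 mL
DEFAULT_WALL_THICKNESS = 10.0  # mm; ED LV mass ~150 g


@dataclass
class FactorSDs:
    """Population SDs of the six generative factors."""

    size: float = 0.08  # multiplicative scale about 1
    apex_pointedness: float = 0.15  # exponent offset shaping the apex
    basal_tilt_deg: float = 4.0  # rigid tilt of the long axis
    elongation: float = 0.06  # multiplicative long-axis scale about 1
    wall_thickness_mm: float = 1.5  # additive wall-thickness offset
    mid_diameter_mm: float = 1.5  # additive mid-cavity radial bulge

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.size,
                self.apex_pointedness,
                self.basal_tilt_deg,
                self.elongation,
                self.wall_thickness_mm,
                self.mid_diameter_mm,
            ]
        )


FACTOR_NAMES = (
    "size",
    "apex_pointedness",
    "basal_tilt_deg",
    "elongation",
    "wall_thickness_mm",
    "mid_diameter_mm",
)


@dataclass
class MaceEffect:
    """Shift applied to ES-phase parameters of outcome-positive subjects.

    Positive cases contract less (higher residual ES volume), lose
    longitudinal shortening, and dilate at the mid-cavity: a mix of volume
    and non-volume shape components.
    """

    contraction: float = -0.10
    elongation: float = -0.06
    mid_diameter_mm: float = 1.5


@dataclass
class CohortConfig:
    n_subjects: int = 200
    n_rings: int = DEFAULT_N_RINGS
    n_circ: int = DEFAULT_N_CIRC
    endo_semi_axes: tuple[float, float, float] = DEFAULT_ENDO_SEMI_AXES
    wall_thickness_mm: float = DEFAULT_WALL_THICKNESS
    factor_sds: FactorSDs = field(default_factory=FactorSDs)
    es_contraction: float = 0.45  # mean ES cavity-volume reduction fraction
    es_contraction_sd: float = 0.07
    es_wall_thickening: float = 0.0  # extra thickening beyond volume conservation
    mace_prevalence: float = 74.0 / 1021.0
    mace_effect: MaceEffect = field(default_factory=MaceEffect)
    misalignment_sd_mm: float = 0.5
    misalignment_band_mm: float = 8.0
    split_fractions: tuple[float, float, float] = (0.70, 0.05, 0.25)
    seed: int = 0
    allow_nonstandard_resolution: bool = False

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if not 0.0 <= self.mace_prevalence <= 1.0:
            raise ConfigurationError("mace_prevalence must be in [0, 1]")
        if any(s < 0 for s in self.factor_sds.as_array()):
            raise ConfigurationError("factor SDs must be non-negative")
        if self.misalignment_sd_mm < 0:
            raise ConfigurationError("misalignment SD must be non-negative")


@dataclass
class SyntheticCohort:
    ed: MeshDataset
    es: MeshDataset
    factors: pd.DataFrame  # one row per subject, generative-factor values
    labels: np.ndarray  # binary MACE outcome
    split: np.ndarray  # train/val/test per subject
    template: Mesh
    config: CohortConfig


# ---------------------------------------------------------------------------
# Template construction
# ---------------------------------------------------------------------------

def template_vertex_count(n_rings: int, n_circ: int) -> int:
    return 2 * (1 + (n_rings + 1) * n_circ)


def build_template(
    n_rings: int = DEFAULT_N_RINGS,
    n_circ: int = DEFAULT_N_CIRC,
    endo_semi_axes: tuple[float, float, float] = DEFAULT_ENDO_SEMI_AXES,
    wall_thickness_mm: float = DEFAULT_WALL_THICKNESS,
    allow_nonstandard_resolution: bool = False,
    phase: str = "unspecified",
) -> Mesh:
    """Truncated half-ellipsoid LV shell with endo/epi/basal-rim labels.

    Raises ``ConfigurationError`` when the grid does not yield the canonical
    2,450-vertex template, unless explicitly overridden for scaled-down use.
    """
    v_count = template_vertex_count(n_rings, n_circ)
    if v_count != mesh_core.TEMPLATE_VERTEX_COUNT and not allow_nonstandard_resolution:
        raise ConfigurationError(
            f"grid ({n_rings} rings x {n_circ}) yields {v_count} vertices, not "
            f"{mesh_core.TEMPLATE_VERTEX_COUNT}; pass allow_nonstandard_resolution=True for scaled-down meshes"
        )
    return _build_shell(
        n_rings,
        n_circ,
        endo_semi_axes,
        tuple(s + wall_thickness_mm for s in endo_semi_axes),
        apex_pointedness=0.0,
        mid_bulge_endo_mm=0.0,
        mid_bulge_epi_mm=0.0,
        phase=phase,
    )


def _surface_points(
    semi_axes: tuple[float, float, float],
    n_rings: int,
    n_circ: int,
    apex_pointedness: float,
    mid_bulge_mm: float,
) -> np.ndarray:
    """Vertices of one truncated-ellipsoid surface: apex pole then rings apex->base.

    The apex sits at z = -c, the basal plane at z = 0.  ``apex_pointedness``
    exponentiates the longitudinal profile (positive = sharper apex);
    ``mid_bulge_mm`` adds a radial bump peaking mid-ventricle and vanishing
    at both apex and base.
    """
    a, b, c = semi_axes
    i = np.arange(1, n_rings + 2)  # rings 1..n_rings+1 (last = basal rim)
    theta = 0.5 * math.pi * i / (n_rings + 1)
    p = 1.0 + max(apex_pointedness, -0.8)
    z = -c * np.cos(theta) ** p
    bump = mid_bulge_mm * np.sin(2.0 * theta)  # 0 at apex and base
    phi = 2.0 * math.pi * np.arange(n_circ) / n_circ
    x = (a * np.sin(theta)[:, None] + bump[:, None]) * np.cos(phi)[None, :]
    y = (b * np.sin(theta)[:, None] + bump[:, None]) * np.sin(phi)[None, :]
    zz = np.broadcast_to(z[:, None], x.shape)
    pts = np.stack([x, y, zz], axis=-1).reshape(-1, 3)
    apex = np.array([[0.0, 0.0, -c]])
    return np.concatenate([apex, pts])


def _surface_faces(n_rings: int, n_circ: int, offset: int, flip: bool) -> np.ndarray:
    """Triangles of one surface (apex fan + quad strips), indices offset."""
    faces = []
    ring = lambda r: offset + 1 + r * n_circ  # first vertex of ring r (0-based rings)
    for j in range(n_circ):
        jn = (j + 1) % n_circ
        faces.append([offset, ring(0) + j, ring(0) + jn])
    for r in range(n_rings):  # strip between ring r and r+1
        for j in range(n_circ):
            jn = (j + 1) % n_circ
            a0, a1 = ring(r) + j, ring(r) + jn
            b0, b1 = ring(r + 1) + j, ring(r + 1) + jn
            faces.append([a0, b0, b1])
            faces.append([a0, b1, a1])
    f = np.asarray(faces, dtype=np.int64)
    if flip:
        f = f[:, [0, 2, 1]]
    return f


def _build_shell(
    n_rings: int,
    n_circ: int,
    endo_axes: tuple[float, float, float],
    epi_axes: tuple[float, float, float],
    apex_pointedness: float,
    mid_bulge_endo_mm: float,
    mid_bulge_epi_mm: float,
    phase: str,
) -> Mesh:
    endo = _surface_points(endo_axes, n_rings, n_circ, apex_pointedness, mid_bulge_endo_mm)
    epi = _surface_points(epi_axes, n_rings, n_circ, apex_pointedness, mid_bulge_epi_mm)
    n_per = len(endo)
    vertices = np.concatenate([endo, epi])

    # Endo surface faces oriented inward-as-stored, epi outward; consistent
    # orientation within each surface is all the volume computation needs.
    f_endo = _surface_faces(n_rings, n_circ, offset=0, flip=False)
    f_epi = _surface_faces(n_rings, n_circ, offset=n_per, flip=True)
    # Basal annulus between the two rim rings (last ring of each surface).
    rim_endo = 1 + n_rings * n_circ
    rim_epi = n_per + 1 + n_rings * n_circ
    annulus = []
    for j in range(n_circ):
        jn = (j + 1) % n_circ
        a0, a1 = rim_endo + j, rim_endo + jn
        b0, b1 = rim_epi + j, rim_epi + jn
        annulus.append([a0, b1, b0])
        annulus.append([a0, a1, b1])
    faces = np.concatenate([f_endo, f_epi, np.asarray(annulus, dtype=np.int64)])

    labels = np.empty(2 * n_per, dtype=np.int64)
    labels[:n_per] = ENDOCARDIAL
    labels[n_per:] = EPICARDIAL
    labels[rim_endo : rim_endo + n_circ] = BASAL_RIM
    labels[rim_epi : rim_epi + n_circ] = BASAL_RIM

    mesh = Mesh(vertices, faces, labels, phase)
    mesh.validate()
    return mesh


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def add_misalignment(
    mesh: Mesh,
    sd_mm: float,
    rng: np.random.Generator | int,
    band_mm: float = 8.0,
) -> Mesh:
    """Rigidly shift short-axis bands in-plane by Gaussian offsets.

    Vertices are grouped into bands of height ``band_mm`` along z (the
    long/slice axis); each band receives one iid N(0, sd^2) shift in x and y,
    emulating breath-hold slice misalignment.  ``sd_mm = 0`` is the identity.
    """
    if sd_mm < 0:
        raise ConfigurationError("misalignment SD must be >= 0")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if sd_mm == 0:
        return mesh.copy()
    z = mesh.vertices[:, 2]
    band = np.floor((z - z.min()) / band_mm).astype(np.int64)
    n_bands = int(band.max()) + 1
    shifts = rng.normal(0.0, sd_mm, size=(n_bands, 2))
    out = mesh.vertices.copy()
    out[:, :2] += shifts[band]
    return mesh.with_vertices(out)


def _tilt(vertices: np.ndarray, tilt_deg: float) -> np.ndarray:
    """Rigid rotation about the x-axis through the basal-plane origin."""
    t = math.radians(tilt_deg)
    rot = np.array([[1, 0, 0], [0, math.cos(t), -math.sin(t)], [0, math.sin(t), math.cos(t)]])
    return vertices @ rot.T


def _subject_mesh(
    cfg: CohortConfig,
    size: float,
    apex: float,
    tilt_deg: float,
    elongation: float,
    wall_mm: float,
    mid_mm: float,
    contraction: float,
    es_elong_shift: float,
    es_mid_shift_mm: float,
    phase: str,
    rng: np.random.Generator,
) -> Mesh:
    a0, b0, c0 = cfg.endo_semi_axes
    if phase == "ED":
        endo = (a0, b0, c0 * (1.0 + elongation))
        wall = max(cfg.wall_thickness_mm + wall_mm, 2.0)
        bulge = mid_mm
    else:
        # Cavity contraction: radial scaling stronger than longitudinal,
        # total cavity-volume factor (1 - contraction).  The wall thickens
        # to conserve myocardial volume (incompressible muscle): thickness
        # scales with the inverse of the approximate endo surface-area
        # scale, times any extra configured thickening.
        f = float(np.clip(contraction, 0.05, 0.8))
        s_r = (1.0 - f) ** (3.0 / 8.0)
        s_z = (1.0 - f) ** (1.0 / 4.0)
        endo = (a0 * s_r, b0 * s_r, c0 * (1.0 + elongation + es_elong_shift) * s_z)
        area_scale = (s_r * s_r + 2.0 * s_r * s_z) / 3.0
        wall = max(
            (cfg.wall_thickness_mm + wall_mm) / area_scale * (1.0 + cfg.es_wall_thickening), 2.0
        )
        bulge = mid_mm + es_mid_shift_mm
    epi = tuple(s + wall for s in endo)
    mesh = _build_shell(cfg.n_rings, cfg.n_circ, endo, epi, apex, bulge, bulge, phase)
    verts = _tilt(mesh.vertices * size, tilt_deg)
    mesh = mesh.with_vertices(verts)
    if cfg.misalignment_sd_mm > 0:
        mesh = add_misalignment(mesh, cfg.misalignment_sd_mm, rng, cfg.misalignment_band_mm)
    return mesh


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw a corresponded ED/ES cohort with outcome labels and splits.

    Fully reproducible from ``config.seed``: factor draws, outcome
    assignment, misalignment artifacts and split shuffling all come from one
    seeded generator in a fixed order.
    """
    cfg = config
    if not cfg.allow_nonstandard_resolution and template_vertex_count(cfg.n_rings, cfg.n_circ) != mesh_core.TEMPLATE_VERTEX_COUNT:
        raise ConfigurationError("cohort grid must yield the 2,450-vertex template (or set allow_nonstandard_resolution)")
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_subjects
    sds = cfg.factor_sds.as_array()
    factors = rng.normal(0.0, 1.0, size=(n, 6)) * sds[None, :]
    contraction = cfg.es_contraction + rng.normal(0.0, cfg.es_contraction_sd, size=n)

    n_pos = int(round(n * cfg.mace_prevalence))
    labels = np.zeros(n, dtype=np.int64)
    pos_idx = rng.choice(n, size=n_pos, replace=False)
    labels[pos_idx] = 1

    eff = cfg.mace_effect
    es_contr = contraction + labels * eff.contraction
    es_elong_shift = labels * eff.elongation
    es_mid_shift = labels * eff.mid_diameter_mm

    template = build_template(
        cfg.n_rings,
        cfg.n_circ,
        cfg.endo_semi_axes,
        cfg.wall_thickness_mm,
        allow_nonstandard_resolution=cfg.allow_nonstandard_resolution,
    )

    ed_meshes, es_meshes = [], []
    subject_ids = [f"subj{idx:04d}" for idx in range(n)]
    for idx in range(n):
        size = 1.0 + factors[idx, 0]
        args = dict(
            size=max(size, 0.5),
            apex=factors[idx, 1],
            tilt_deg=factors[idx, 2],
            elongation=factors[idx, 3],
            wall_mm=factors[idx, 4],
            mid_mm=factors[idx, 5],
            contraction=es_contr[idx],
            es_elong_shift=float(es_elong_shift[idx]),
            es_mid_shift_mm=float(es_mid_shift[idx]),
        )
        ed_meshes.append(_subject_mesh(cfg, phase="ED", rng=rng, **args))
        es_meshes.append(_subject_mesh(cfg, phase="ES", rng=rng, **args))

    split = split_dataset(labels, cfg.split_fractions, stratify_by_label=True, seed=cfg.seed)

    table = pd.DataFrame(factors, columns=list(FACTOR_NAMES), index=subject_ids)
    table["es_contraction"] = es_contr
    table["mace"] = labels
    table["split"] = split

    ed = MeshDataset(ed_meshes, subject_ids, labels=labels, split=split.copy())
    es = MeshDataset(es_meshes, subject_ids, labels=labels, split=split.copy())
    return SyntheticCohort(ed=ed, es=es, factors=table, labels=labels, split=split, template=template, config=cfg)


def split_dataset(
    labels: np.ndarray,
    fractions: tuple[float, float, float] = (0.70, 0.05, 0.25),
    stratify_by_label: bool = True,
    seed: int = 0,
) -> np.ndarray:
    """Assign train/val/test with largest-remainder rounding, stratified by label.

    Split sizes follow largest-remainder rounding of ``n * fraction`` overall
    and within each class, keeping per-split prevalence within one case of
    the global prevalence.
    """
    labels = np.asarray(labels, dtype=np.int64)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigurationError(f"split fractions must sum to 1, got {fractions}")
    n = len(labels)
    rng = np.random.default_rng(seed)
    names = np.array(["train", "val", "test"], dtype=object)
    out = np.empty(n, dtype=object)

    sizes_total = _largest_remainder(n, fractions)
    if stratify_by_label and labels.any() and not labels.all():
        pos = np.flatnonzero(labels == 1)
        neg = np.flatnonzero(labels == 0)
        sizes_pos = _largest_remainder(len(pos), fractions)
        sizes_neg = sizes_total - sizes_pos
        if (sizes_neg < 0).any():  # tiny-n degenerate corner
            sizes_neg = _largest_remainder(len(neg), fractions)
        for idx, sizes in ((pos, sizes_pos), (neg, sizes_neg)):
            perm = rng.permutation(idx)
            bounds = np.cumsum(sizes)[:-1]
            for name, chunk in zip(names, np.split(perm, bounds)):
                out[chunk] = name
        if (sizes_pos == 0).any() and len(pos) > 0:
            import warnings

            warnings.warn("some split receives zero positive cases (small-n degenerate stratification)")
    else:
        perm = rng.permutation(n)
        bounds = np.cumsum(sizes_total)[:-1]
        for name, chunk in zip(names, np.split(perm, bounds)):
            out[chunk] = name
    return out


def _largest_remainder(n: int, fractions) -> np.ndarray:
    exact = np.asarray(fractions) * n
    base = np.floor(exact).astype(np.int64)
    short = n - base.sum()
    order = np.argsort(-(exact - base), kind="stable")
    base[order[:short]] += 1
    return base


# ---------------------------------------------------------------------------
# Disk output
# ---------------------------------------------------------------------------

def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> Path:
    """Write per-subject PLY pairs plus labels/factors/splits CSV tables."""
    out = Path(out_dir)
    (out / "meshes").mkdir(parents=True, exist_ok=True)
    for sid, ed_m, es_m in zip(cohort.ed.subject_ids, cohort.ed.meshes, cohort.es.meshes):
        mesh_core.write_mesh(ed_m, out / "meshes" / f"{sid}_ED.ply")
        mesh_core.write_mesh(es_m, out / "meshes" / f"{sid}_ES.ply")
    pd.DataFrame({"subject_id": cohort.ed.subject_ids, "mace": cohort.labels}).to_csv(out / "labels.csv", index=False)
    cohort.factors.rename_axis("subject_id").to_csv(out / "factors.csv")
    pd.DataFrame({"subject_id": cohort.ed.subject_ids, "split": cohort.split}).to_csv(out / "splits.csv", index=False)
    return out
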