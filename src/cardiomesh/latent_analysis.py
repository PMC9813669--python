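"""Latent-space structure: per-dimension activity, traversals, subgroup means.

The *activity* of a latent dimension is the variance, across subjects, of
its posterior mean.  Dimensions the model actually uses to encode population
variability have activity well above zero; collapsed (prior-matching)
dimensions have activity near zero.  Activities are reported both raw and as
percentages of total activity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DimensionError, EmptyInputError
from .mesh_core import Mesh, MeshDataset
from .mesh_vae import LatentCode, MeshVAEModel, decode, encode_dataset

#: Dimensions below this share of total activity are reported as inactive.
ACTIVITY_THRESHOLD_PCT = 1.0


@dataclass
class ActivityProfile:
    activity: np.ndarray  # per-dimension variance of posterior means
    percentage: np.ndarray  # normalized to sum to 100
    ordering: np.ndarray  # dimensions sorted by descending percentage
    degenerate: bool = False  # all codes identical -> percentages undefined

    def n_active(self, threshold_pct: float = ACTIVITY_THRESHOLD_PCT) -> int:
        return int((self.percentage > threshold_pct).sum())

    def as_frame(self) -> pd.DataFrame:
        rank = np.empty_like(self.ordering)
        rank[self.ordering] = np.arange(1, len(self.ordering) + 1)
        return pd.DataFrame(
            {
                "dim": np.arange(len(self.activity)),
                "activity": self.activity,
                "percentage": self.percentage,
                "rank": rank,
            }
        )


def _mu_matrix(codes) -> np.ndarray:
    if isinstance(codes, np.ndarray):
        return codes
    return np.stack([c.mu for c in codes])


def latent_activity(codes: list[LatentCode] | np.ndarray) -> ActivityProfile:
    """Per-dimension variance of posterior means across subjects.

    Accepts LatentCodes or a pre-stacked (n, latent) matrix of means.
    Identical codes give an all-zero, explicitly degenerate profile.
    """
    mu = _mu_matrix(codes)
    if mu.ndim != 2:
        raise DimensionError("codes must stack to an (n, latent) matrix")
    if len(mu) < 2:
        raise EmptyInputError("activity needs at least 2 codes")
    act = mu.var(axis=0)
    total = act.sum()
    if total <= 0:
        return ActivityProfile(
            activity=act, percentage=np.zeros_like(act), ordering=np.arange(len(act)), degenerate=True
        )
    pct = 100.0 * act / total
    return ActivityProfile(activity=act, percentage=pct, ordering=np.argsort(-pct, kind="stable"))


def traverse(
    model: MeshVAEModel,
    codes: list[LatentCode] | np.ndarray,
    dim: int,
    n_steps: int = 7,
    sd_range: float = 3.0,
) -> list[Mesh]:
    """Decode a +-``sd_range``-SD traversal of one latent dimension.

    All other components stay at the population mean of the posterior means;
    the traversed component moves over a symmetric ``n_steps`` grid.  With an
    odd ``n_steps`` the center mesh is the decoded population mean itself.
    """
    mu = _mu_matrix(codes)
    if not 0 <= dim < mu.shape[1]:
        raise DimensionError(f"dim {dim} out of range for latent size {mu.shape[1]}")
    center = mu.mean(axis=0)
    sd = mu[:, dim].std()
    meshes = []
    for step in np.linspace(-sd_range, sd_range, n_steps):
        z = center.copy()
        z[dim] += step * sd
        meshes.append(decode(model, z))
    return meshes


def traversal_extent(meshes: list[Mesh]) -> float:
    """Max pairwise mean vertex displacement across a traversal (mm)."""
    coords = np.stack([m.vertices for m in meshes])
    ext = 0.0
    for i in range(len(coords)):
        for j in range(i + 1, len(coords)):
            d = np.linalg.norm(coords[i] - coords[j], axis=1).mean()
            ext = max(ext, d)
    return float(ext)


def subgroup_mean_shape(
    model: MeshVAEModel,
    dataset: MeshDataset,
    labels: np.ndarray | None = None,
) -> dict[int, Mesh]:
    """Decode the mean posterior-mean vector of each label group.

    Mirrors the subgroup comparison workflow: encode every subject, average
    the latent means within each outcome group, decode the group averages
    with the shared decoder.
    """
    labels = dataset.labels if labels is None else np.asarray(labels)
    if labels is None:
        raise EmptyInputError("labels required (either on the dataset or explicitly)")
    mu = encode_dataset(model, dataset)
    out: dict[int, Mesh] = {}
    for group in np.unique(labels):
        out[int(group)] = decode(model, mu[labels == group].mean(axis=0))
    return out


def write_activity_csv(profile: ActivityProfile, path: str | Path) -> Path:
    path = Path(path)
    profile.as_frame().to_csv(path, index=False)
    return path
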