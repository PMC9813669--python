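"""Shared fixtures: small meshes, scaled-down cohorts, and one trained model pair.

All fixtures are generated programmatically; nothing is loaded from disk.
The expensive trained-model fixtures are session-scoped so the
reconstruction, latent-analysis, generation and classification tests share
a single training run per cardiac phase.
"""

from __future__ import annotations

import numpy as np
import pytest
import trimesh

from cardiomesh import mesh_core as mc
from cardiomesh import mesh_sampling as ms
from cardiomesh import mesh_vae as mv
from cardiomesh import synthetic_population as sp


@pytest.fixture
def tetra() -> mc.Mesh:
    verts = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
    faces = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return mc.Mesh(verts, faces)


@pytest.fixture
def icosphere() -> mc.Mesh:
    ico = trimesh.creation.icosphere(subdivisions=4, radius=10.0)
    return mc.Mesh(np.asarray(ico.vertices), np.asarray(ico.faces))


@pytest.fixture
def small_icosphere() -> mc.Mesh:
    ico = trimesh.creation.icosphere(subdivisions=1, radius=10.0)
    return mc.Mesh(np.asarray(ico.vertices), np.asarray(ico.faces))


@pytest.fixture(scope="session")
def template() -> mc.Mesh:
    return sp.build_template()


@pytest.fixture(scope="session")
def small_template() -> mc.Mesh:
    """Scaled-down LV shell (114 vertices) for fast structural tests."""
    return sp.build_template(n_rings=6, n_circ=8, allow_nonstandard_resolution=True)


@pytest.fixture(scope="session")
def small_cohort() -> sp.SyntheticCohort:
    cfg = sp.CohortConfig(
        n_subjects=24,
        n_rings=6,
        n_circ=8,
        allow_nonstandard_resolution=True,
        seed=11,
    )
    return sp.generate_cohort(cfg)


@pytest.fixture(scope="session")
def hierarchy(template: mc.Mesh) -> ms.SamplingHierarchy:
    return ms.build_hierarchy(template, n_levels=4, factor=4.0)


@pytest.fixture(scope="session")
def study_cohort() -> sp.SyntheticCohort:
    """The scaled-down study cohort: n=200 subjects, default factor SDs."""
    return sp.generate_cohort(sp.CohortConfig(n_subjects=200, seed=7))


def _train_phase(cohort: sp.SyntheticCohort, hierarchy: ms.SamplingHierarchy, phase: str) -> mv.MeshVAEModel:
    dataset = cohort.ed if phase == "ED" else cohort.es
    cfg = mv.VAEConfig(epochs=60, seed=7)
    stats = mc.fit_standardization(dataset)
    model = mv.MeshVAEModel(hierarchy, cfg, stats, phase=phase)
    mv.train(model, dataset, cfg)
    return model


@pytest.fixture(scope="session")
def trained_ed_model(study_cohort, hierarchy) -> mv.MeshVAEModel:
    return _train_phase(study_cohort, hierarchy, "ED")


@pytest.fixture(scope="session")
def trained_es_model(study_cohort, hierarchy) -> mv.MeshVAEModel:
    return _train_phase(study_cohort, hierarchy, "ES")
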