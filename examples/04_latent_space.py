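"""Latent activity profile and +-3 SD shape traversals.

Trains a small model, ranks latent dimensions by activity (variance of the
posterior means across subjects), and decodes a traversal along the most
and least active dimensions to show how much shape change each encodes.
"""

import numpy as np

from cardiomesh import latent_analysis as la
from cardiomesh import mesh_core as mc
from cardiomesh import mesh_sampling as ms
from cardiomesh import mesh_vae as mv
from cardiomesh import synthetic_population as sp

cohort = sp.generate_cohort(sp.CohortConfig(n_subjects=60, seed=7))
hierarchy = ms.build_hierarchy(cohort.template)
config = mv.VAEConfig(epochs=20, seed=7)
model = mv.MeshVAEModel(hierarchy, config, mc.fit_standardization(cohort.ed), phase="ED")
mv.train(model, cohort.ed, config)

mu = mv.encode_dataset(model, cohort.ed)
profile = la.latent_activity(mu)
print(profile.as_frame().sort_values("rank").head(8).to_string(index=False))
print(f"dimensions above 1% of total activity: {profile.n_active()}")

top, bottom = profile.ordering[0], profile.ordering[-1]
for dim in (top, bottom):
    meshes = la.traverse(model, mu, dim=int(dim), n_steps=7)
    extent = la.traversal_extent(meshes)
    print(f"dim {dim}: max mean vertex displacement over +-3 SD traversal = {extent:.2f} mm")
# The most active dimension sweeps a large, anatomically coherent shape
# range; the least active one barely moves the mesh.
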