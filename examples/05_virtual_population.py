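"""Generate a virtual cohort from the trained decoder and check realism.

Fits the latent sampler to the training set's posterior means, decodes 200
virtual subjects, and compares the clinical metrics of the generated
population against the real (synthetic) training population.
"""

from cardiomesh import mesh_core as mc
from cardiomesh import mesh_sampling as ms
from cardiomesh import mesh_vae as mv
from cardiomesh import population_gen as pg
from cardiomesh import synthetic_population as sp

cohort = sp.generate_cohort(sp.CohortConfig(n_subjects=60, seed=7))
hierarchy = ms.build_hierarchy(cohort.template)
config = mv.VAEConfig(epochs=20, seed=7)
model = mv.MeshVAEModel(hierarchy, config, mc.fit_standardization(cohort.ed), phase="ED")
mv.train(model, cohort.ed, config)

train_set = cohort.ed.split_subset("train")
sampler = pg.fit_latent_sampler(mv.encode_dataset(model, train_set))
virtual = pg.generate_population(model, sampler, n=200, seed=3)

print("generated population:")
print(pg.population_clinical_summary(virtual).as_frame().round(1).to_string())
print("training population:")
print(pg.population_clinical_summary(train_set).as_frame().round(1).to_string())
# Means agree within a few percent; the generated SD is somewhat smaller
# than the real one (the usual mild variance shrinkage of VAE decoders).
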