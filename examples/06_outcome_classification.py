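"""Predict the MACE outcome from ES latent shape features vs. ES volume.

The synthetic cohort plants the outcome effect in ES shape (reduced
contraction, lost longitudinal shortening, mid-cavity dilation).  A ridge
logistic model on latent posterior means is compared with the clinical
single-feature baseline (ES endocardial volume) under stratified 10-fold
cross-validation.
"""

from cardiomesh import mace_classifier as mcl
from cardiomesh import mesh_core as mc
from cardiomesh import mesh_sampling as ms
from cardiomesh import mesh_vae as mv
from cardiomesh import synthetic_population as sp

cohort = sp.generate_cohort(sp.CohortConfig(n_subjects=120, seed=7))
hierarchy = ms.build_hierarchy(cohort.template)
config = mv.VAEConfig(epochs=20, seed=7)
model = mv.MeshVAEModel(hierarchy, config, mc.fit_standardization(cohort.es), phase="ES")
mv.train(model, cohort.es, config)

latent = mcl.latent_features(model, cohort.es)
volume = mcl.es_volume_baseline(cohort.es)

for name, feats in (("latent (16-dim)", latent), ("ES volume", volume)):
    result = mcl.stratified_cv_auroc(feats, cohort.labels, k=5, seed=11, feature_set=name)
    print(f"{name:16s} AUROC {result.mean_auroc:.3f} (+-{result.sd_auroc:.3f}) over {result.n_folds} folds")
# AUROC is the probability a random positive outranks a random negative.
# At this demonstration scale (120 subjects, 20 epochs) the two feature
# sets are close and fold scores are noisy (~14 positives in total); at
# the study scale used by the test suite (200 subjects, 60 epochs) the
# latent features clearly beat the volume baseline because they also
# capture the planted non-volume shape components.
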