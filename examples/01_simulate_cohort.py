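"""Generate a small synthetic LV cohort and inspect its clinical metrics.

Builds 30 paired ED/ES left-ventricular surface meshes with population
variation in six anatomical factors, prints per-phase cavity volume and
myocardial mass, and shows the outcome/split bookkeeping.
"""

import numpy as np

from cardiomesh import mesh_core as mc
from cardiomesh import synthetic_population as sp

cohort = sp.generate_cohort(sp.CohortConfig(n_subjects=30, seed=7))

print(f"template: {cohort.template.n_vertices} vertices, {cohort.template.n_faces} faces")
print(f"subjects: {len(cohort.ed)}  MACE-positive: {int(cohort.labels.sum())}")
print(f"splits: {dict(zip(*np.unique(cohort.split, return_counts=True)))}")

for phase, ds in (("ED", cohort.ed), ("ES", cohort.es)):
    vols = [mc.enclosed_volume(m, "endocardial") for m in ds.meshes]
    masses = [mc.clinical_metrics(m)["lv_mass_g"] for m in ds.meshes[:5]]
    print(
        f"{phase}: endo volume {np.mean(vols):6.1f} (+-{np.std(vols):4.1f}) mL; "
        f"first masses {np.round(masses, 1)} g"
    )

# ES cavities are smaller than ED cavities for every subject (systolic
# contraction); the volume spread reflects the size/elongation factors.
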