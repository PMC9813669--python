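# Methods

This note documents the models, conventions and design choices behind
`cardiomesh`, in the order data flows through the package.

## Synthetic LV cohorts (`synthetic_population`)

**What it emulates.**  Cohorts of corresponded LV surface meshes of the
kind produced by cine-MRI segmentation followed by template-mesh fitting:
one mesh per subject per cardiac phase (ED = end-diastole, ES =
end-systole), identical connectivity across subjects, a rare binary
outcome (MACE), and residual slice-misalignment artifacts from breath-hold
acquisitions.

**Template.**  A truncated half-ellipsoid shell.  Each surface
(endocardial, epicardial) is an apex pole plus 50 latitude rings of 24
vertices; a 51st ring per surface carries the basal-rim label and the two
rim rings are joined by a flat basal annulus: 2·(1 + 51·24) = 2,450
vertices, matching the canonical corresponded-mesh resolution.  Default
geometry: endocardial semi-axes a = b = 27 mm, c = 85 mm, wall thickness
10 mm.  This yields an ED cavity volume of ≈ 128 mL and an LV mass of
≈ 148 g, inside the normal-to-post-infarct clinical range.  The
tessellation pattern itself is a package convention; only the vertex count
is canonical.

**Generative factors.**  Six independent Gaussians per subject, SDs chosen
to give clinically plausible spread:

| factor | unit | default SD | effect |
| --- | --- | --- | --- |
| size | × | 0.08 | global scale |
| apex pointedness | – | 0.15 | exponent on the longitudinal profile |
| basal tilt | deg | 4.0 | rigid rotation of the long axis |
| elongation | × | 0.06 | long-axis scale |
| wall thickness | mm | 1.5 | endo→epi offset |
| mid-cavity diameter | mm | 1.5 | radial bulge peaking mid-ventricle |

**ED→ES pairing.**  ES meshes reuse the subject's parameters with a cavity
contraction fraction f ~ N(0.45, 0.07²) (clipped to [0.05, 0.8]); radial
scaling (1−f)^{3/8} is stronger than longitudinal (1−f)^{1/4}, their
product giving a cavity-volume factor of exactly 1−f before the additive
bulge.  ES wall thickness scales with the inverse of the approximate endo
surface-area scale so that myocardial volume is conserved (incompressible
muscle); `es_wall_thickening` adds extra fractional thickening on top
(default 0).  Every subject therefore has a smaller, thicker-walled ES
shape.

**Outcome.**  Exactly `round(n · prevalence)` positives (default
prevalence 74/1021 ≈ 7.2%), drawn without replacement.  Positives receive
an ES-only effect: contraction −0.10, elongation −0.06, mid-cavity
diameter +1.5 mm — a deliberate mix of volume and non-volume shape
components, so that latent shape features carry information a pure
ES-volume baseline cannot.

**Misalignment artifact.**  Vertices are grouped into 8 mm short-axis
bands; each band gets one rigid in-plane N(0, 0.5² mm²) shift.  0.5 mm is
below the 1.36 mm pixel resolution of the emulated acquisitions.  This
noise is *not* part of the six-factor manifold and is only partially
encodable by a 16-dim latent space.

**Splits.**  70/5/25 train/val/test by largest-remainder rounding,
stratified per class, so per-split prevalence is within one case of the
global prevalence (e.g. n = 1021 → 715/51/255).

**What the generator does not emulate.**  Infarct scar geometry, regional
wall-motion abnormalities, papillary muscles, valve planes, multi-center
scanner effects, and any correlation structure between factors.  Passing
tests on this cohort show the pipeline's mechanics and its behavior under
a known low-dimensional ground truth; they do not certify accuracy on
clinical meshes.

## Mesh hierarchy (`mesh_sampling`)

Garland–Heckbert quadric-error edge collapse restricted to vertex-subset
collapses: the removed endpoint merges into the kept endpoint at its
original position, so coarse vertices are a subset of fine vertices and the
down-transform is pure vertex selection.  Area-weighted face quadrics;
boundary edges add perpendicular constraint quadrics (weight 100) so open
rims do not collapse inward.  Candidates are ordered by (error, removed
index, kept index) for cross-platform determinism; collapses that would
flip or degenerate a surviving face are rejected.  If the queue empties
before the target count, the best achieved resolution is returned with a
warning.

Up-transforms reinsert each removed vertex with the barycentric weights of
its closest-point projection onto the nearest coarse triangle (clamped, so
every row is a convex combination).  This is exact for affine vertex
fields on planar regions; on the LV template one down/up round trip costs
≈ 0.06 mm MSD (< 0.1% of the long axis).

Defaults: 4 levels at factor 4 (2450 → 613 → 154 → 39).  These are package
conventions chosen to keep the coarsest level informative; both are
configurable.  Serialization is a directory of MatrixMarket text files
(precision 17, so float64 survives bit-exactly) plus PLY level meshes; a
content hash guards reloads.

## Spectral graph convolution (`graph_conv`)

Symmetric normalized Laplacian `L = I − D^{−1/2} A D^{−1/2}` from the mesh
edge graph (no self-loops; isolated vertices get degree floored at 1 with
a warning).  The filter scale uses λ_max = 2, the spectral upper bound for
normalized Laplacians, instead of a per-graph eigensolve — deterministic,
cheap, and standard.  Order-5 Chebyshev filters are evaluated by the
three-term recurrence; equivalence with the dense eigendecomposition
filter is property-tested on random graphs.

## Mesh VAE (`mesh_vae`)

Architecture (defaults): encoder = [conv 3→16, pool, conv 16→16, pool,
conv 16→16, pool, conv 16→32] with ReLU after every conv, then a fully
connected map from the 39×32 coarsest features to (μ, log σ²) ∈ R^{16+16};
decoder mirrors it and ends in a linear conv to 3 coordinate channels.
72,035 trainable parameters at the defaults (reported at build).

Conventions and numerical choices:

- **Standardization.**  Per-vertex-coordinate mean/SD computed on the
  *training split only* (requesting any other split raises a data-leakage
  error); SDs floored at 1e-8.  The alternative of per-mesh statistics was
  considered and rejected: dataset-level statistics keep the latent space
  in one consistent coordinate frame.  Training and the
  reconstruction loss operate in standardized space; evaluation metrics are
  computed in mm after destandardization.
- **Loss reduction.**  Per mesh: vertex-mean squared coordinate error plus
  β times the KL summed over latent dimensions; batch loss is the mean over
  meshes.  `total = rec + β·kl` holds to machine precision at every epoch
  and is asserted in tests.
- **β schedule.**  Linear (monotonic) from 1e-4 at epoch 0 to 1e-3 at the
  final epoch.  Cyclical variants are deliberately not used.
- **Posterior head init.**  The log-variance head bias starts at −6
  (σ ≈ 0.05): starting near-deterministic avoids the early-training plateau
  where reparameterization noise of σ ≈ 1 swamps the reconstruction
  gradient.
- **log σ² clipping.**  ±15, with zero gradient outside the clip range.
- **Determinism.**  Weight init, batch shuffling and reparameterization
  noise all derive from `config.seed`; identical seeds give identical loss
  histories on one platform.
- **Evaluation.**  Reconstructions use the posterior mean (no sampling).
  Separate models per cardiac phase; a phase tag on the model rejects
  meshes of the other phase.
- **Non-finite losses** abort with the offending epoch/batch and loss
  component.

Checkpoints are single-file `.npz` archives (weights, config, hierarchy
with content hash, standardization stats, training history; versioned
schema).

## Latent analysis (`latent_analysis`)

Activity of dimension u = variance across subjects of μ_u, reported raw
and as percentage of total activity; "contributing" defaults to > 1% of
total (configurable).  Traversals move one component over a symmetric
7-step ±3 SD grid with all others at the population mean.  Subgroup mean
shapes decode the group-averaged μ through the shared decoder.

## Virtual populations (`population_gen`)

Default latent sampler is *encoder-fitted*: independent Gaussians with the
per-dimension mean/SD (sample SD, n−1) of the training posterior means —
it samples where the decoder was actually trained and produces more
realistic anatomies than the standard-normal prior, which is retained as
an explicit mode for comparison.  Population summaries use the population
SD convention (divide by n).  The reference population for fidelity
comparisons is the training split (a reporting choice; the unseen test
split is equally available).

## Outcome classification (`mace_classifier`)

Features: ES-model posterior means (deterministic), or the ES endocardial
volume baseline.  Ridge logistic regression (inverse strength C = 1,
lbfgs), features standardized per fold on training folds only, under
stratified 10-fold CV; k is reduced with a warning if a fold would receive
no positive case.  AUROC uses the rank/concordance formula with 0.5 credit
per tie and is cross-checked in tests against an all-pairs count and an
independent library implementation.

## Problem sizes

The study-scale runs used by the test suite and the acceptance script are
scaled-down analogues chosen as the package's standard benchmark: cohorts
of n = 200 (train/val/test 140/10/50), 60 training epochs, the full
2,450-vertex template, 500-subject virtual populations, and 10-fold CV on
the 200-subject cohort.  Unit and property tests run on a 114-vertex
scaled-down shell (explicit resolution override).

## Known limitations

- At the trained β range (≤ 1e-3) the latent space does not prune itself
  to the six planted factors: activity stays spread over most of the 16
  dimensions (top-6 ≈ 55–57% of total activity, with a visible drop after
  the 6th), and this persists with longer schedules and without the
  misalignment artifact.  Aggressive per-dimension pruning would require a
  substantially larger β than the annealing target used here.
- Reconstruction smooths high-frequency content; band-misalignment
  artifacts are only partially reproduced, which is also why unseen-subject
  MSD sits near (not at) zero.
- The classifier analysis assumes one feature set at a time; no clinical
  covariates, no multi-task training.
- Surface distances are evaluated at mesh vertices (dense and corresponded
  at 2,450 vertices), not by dense surface sampling.
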