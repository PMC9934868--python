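# Methods

`cellmorph` learns a per-cell morphology descriptor from a segmented 3D EM
volume without any labels, and provides the evaluation and exploration
statistics that make such descriptors useful: morphotype classification,
bilateral symmetric-partner ranking, graph-based clustering, and
marker/feature specificity scores. This note records the model, its
assumptions, the tunable parameters, and the design decisions taken where
the design was genuinely open.

## The descriptor model

Each cell is represented by a 480-dimensional vector: six 80-dimensional
embeddings in fixed order — shape, coarse texture and fine texture, for the
cell (cytoplasm) and its nucleus. The components are produced by six
independently trained encoders:

* **Shape** (per compartment): the membrane surface is meshed (marching
  cubes, volume-preserving Laplacian smoothing, remeshed to a face budget),
  points and outward normals are sampled uniformly by area, and a dynamic
  graph convolution network encodes the cloud. Each EdgeConv layer builds a
  k-nearest-neighbour graph in the current feature space, applies a shared
  linear+ELU map to (centre, neighbour − centre) pairs, and max-aggregates
  over neighbours; a fuse layer plus max pooling over points yields a latent
  vector and an MLP head emits 80 features. Max pooling makes the encoder
  invariant to point order; it is *not* mirror-invariant by construction —
  mirror invariance is learned through augmentation.
* **Coarse texture** (per compartment): one nucleus-centred, compartment-
  masked, [0, 1]-normalised crop from a downsampled view of the raw volume
  feeds a 3-block 3D convolutional encoder (channels doubling from the base
  width, ELU activations, 2× max pooling per block), a 1×1×1 convolution to
  80 channels, and **masked global average pooling**: the per-channel mean
  over only those coarse positions whose pooling window contains compartment
  voxels. Empty space therefore never dilutes the embedding; appending
  masked-out margins (aligned to the pooling factor and clear of the
  receptive-field halo) leaves embeddings unchanged, which the tests assert.
* **Fine texture** (per compartment): the compartment bounding box is tiled
  with non-overlapping cubes anchored at the box corner; cubes more than
  half filled by compartment voxels are encoded individually by the same
  architecture and averaged into one 80-vector per cell.

## Training objectives

All encoders are trained with the NT-Xent contrastive loss: a batch of B
source objects yields 2B augmented views ordered so views i and i+B are
positives; the loss is the temperature-scaled cross entropy over cosine
similarities, averaged over all 2B anchors, with self-similarity excluded.
Analytic anchors used in tests: identical embeddings give ln 3 at B = 2 for
any temperature; orthogonal positive pairs at τ = 0.5 give
−ln(e²/(e²+2)) ≈ 0.2395.

Texture encoders additionally train an autoencoder branch: a one-block
decoder (2× nearest-neighbour upsampling + convolutions) reconstructs the
input from the pre-pool 80-channel maps. Because three pooling stages shrink
the input 8× while one decoder block restores only 2×, the reconstruction
target is the input downsampled by local mean to the decoder output shape —
a forced design decision given the asymmetric architecture; the target
resolution is configurable. The total texture loss is a weighted sum of
NT-Xent, reconstruction MSE, and a mean-squared penalty on the bottleneck
embedding (defaults 1, 1, 1e-4: parts stay within an order of magnitude on
phantoms).

Optimisation uses Adam with the reference hyper-parameters as defaults
(shape: lr 2e-4, weight decay 4e-4; texture: lr 1e-4, weight decay 5e-5;
temperature 0.5, the published default of the loss). Validation on a held-out
10% split runs every `eval_every` iterations; a score counts as improved only
if it falls below `improvement_factor` (0.95) times the best so far — the
relative-improvement reading of the protocol — otherwise the learning rate
decays by 0.98 and the best checkpoint is retained. A batch with a single
source has no negatives; the loss is 0 by convention, with a warning.

## Augmentations

Mesh views are precomputed (10 per object in the reference protocol):
handle regions — Euclidean balls around random surface vertices — are
displaced in a random, normal, or negative-normal direction and the
constraint is propagated by a biharmonic displacement field (cotangent
Laplacian bilaplacian solve) or an as-rigid-as-possible local-global solve,
both implemented on scipy.sparse; training then draws two distinct cached
views per object and applies independent anisotropic scaling, rotation and
(with probability 1/2) mirroring. Biharmonic propagation may overshoot the
handle displacement; the documented bound is displacement × (1 + slack) with
slack 1.5. Texture views combine axis flips, right-angle rotations and a
smooth elastic warp (Gaussian control-point grid 4³, order-1 resampling with
edge-value extension so smooth crops keep their mean within 2%); the
compartment mask travels through the same geometric transform so masked
pooling sees the moved support.

Intensity augmentations (brightness/contrast jitter) are deliberately
absent: the encoders are sensitive to intensity shifts and the descriptor is
intended to reflect them.

## Analysis protocols

* **Morphotype classification**: features standardised, agglomerated to 100
  merged columns when wider, multinomial logistic regression (C = 1, lbfgs)
  under stratified 5-fold cross-validation; fold accuracies plus a summed
  confusion matrix with rows = true labels.
* **Bilateral ranking**: each cell's candidate mirror partners are the N
  nearest opposite-side cells to its centroid reflected across the
  mediolateral mid-plane (N = 10 default); the nearest candidate in feature
  space is ranked against all other cells by Euclidean distance (rank 1 =
  nearest; distance ties break to the smaller id); the summary is the median
  rank. The reflection heuristic stands in for an unspecified candidate
  construction; on phantoms the ground-truth partner is always among the
  candidates.
* **Clustering**: the UMAP fuzzy simplicial-set k-NN graph (n_neighbours 20,
  Euclidean) partitioned by Leiden with the constant Potts model at
  resolution γ (0.004 default; subclustering re-runs one cluster at larger
  γ). Both graph construction and Leiden take explicit seeds; same-seed runs
  are bit-identical. The UMAP layout itself is visualisation-only and never
  feeds clustering.
* **Specificity**: for cluster k and variable v, A = mean value in k,
  B = sum in k / total sum, C = 2AB/(A+B) (C = 0 at A+B = 0). For features,
  values are clipped to ±2 (meaningful on standardised tables), mapped
  affinely to [0, 1], and B is divided by the relative cluster size; the
  fixed affine map (not per-feature min-max) keeps a constant feature at
  uniform, non-zero specificity across clusters. Dot-plot selection uses
  C > 0.15 for genes (optional pairwise-difference filter for two-cluster
  plots: drop genes specific in both with |ΔC| < 0.4) and C > 1 for
  features.
* **Representative cell**: member nearest the coordinate-wise median vector;
  **feature extremes**: k lowest/highest cells of one feature; ties to the
  smaller id; an exclusion list (e.g. known merge errors) is honoured.

## The phantom generator

The generator emulates the structure the pipeline assumes about a
whole-body EM atlas — not its appearance. Cells are parametric solids
(sphere, ellipsoid, stellate, flat) with one ellipsoidal nucleus strictly
inside, placed without overlap on one body side and mirrored voxel-exactly
across the mediolateral mid-plane (the last array axis; reflection x →
X−1−x), so every cell has a bilateral partner with identical mirrored shape
but independently sampled texture noise. Cytoplasm textures (uniform /
speckle / vesicular blobs) have class means separated by ≥ 30 of 255
intensity units; chromatin is smooth or granular. `contact_fraction`
controls how many cells are placed face-adjacent to a neighbour (preferring
their own class): at 1 each body side grows one connected patch, at 0 every
cell keeps a one-voxel background gap. Defaults (chosen once as the study
conditions): 30 cell pairs of 3 shape × 2 texture classes on a 96×72×120
grid at (100, 80, 80) nm voxels, cell radii 7–10 voxels — large enough that
every cell yields at least one fine patch at desk resolution — contact
fraction 0.5.

What the phantom does **not** emulate: real EM noise statistics and shading,
neurites, organelle-scale structure beyond blob vesicles, segmentation
errors (beyond an optional label-merge corruption helper), or anisotropic
partial-volume effects. Passing tests therefore demonstrate the pipeline's
mechanics, wiring and statistical protocols — not that the encoders resolve
real ultrastructure.

## Desk-scale study conditions

The end-to-end checks train reduced encoders on one CPU in minutes. Chosen
problem sizes: point clouds of 256 points with k = 10 and hidden width 32;
texture encoders with 8 base channels; coarse crops 24³ (cell) / 16³
(nucleus); fine patches 4³ with a 2-block fine encoder (a 4³ cube only
supports two pooling stages); 6 cached views per mesh; 250 shape / 80
coarse / 100 fine iterations. At this scale the NT-Xent similarities start
compressed near 1 (ELU positivity gives embeddings a large common
component), so the desk protocol uses a sharper temperature (0.1) and larger
learning rate (2e-3) for the shape encoders; texture encoders keep τ = 0.5.
The reference-scale defaults in `TrainConfig`/`ExtractionConfig` are
unchanged by these desk settings.

## Numerical choices and degenerate inputs

* Intensity normalisation divides by the dtype maximum; float inputs are
  assumed already normalised (idempotent).
* A patch exactly half-occupied is excluded (strict inequality).
* Marching cubes runs on a 1-voxel padded mask, guaranteeing closed
  surfaces; non-watertight meshes after repair are an error, not a warning.
* Mesh simplification remeshes on a 2×-downsampled mask rather than
  collapsing edges; watertightness is preserved by construction.
* Zero-variance features standardise to all-zeros.
* Zero-norm embeddings make the cosine similarity undefined and raise.
* Cells failing any extraction stage are excluded from the feature table and
  listed in an exclusion report, never silently dropped.

## Known limitations

* The autodiff engine is minimal and CPU-bound; reference-protocol crop
  sizes (144³/320³) are supported by the extraction code but impractical to
  train here.
* ARAP uses a fixed small number of local-global iterations (5) rather than
  a convergence test.
* The candidate-partner construction for bilateral ranking is a geometric
  stand-in (documented above).
* Fine-texture patch tiling is anchored at the bounding-box corner; features
  are not invariant to sub-patch translations of the cell.
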