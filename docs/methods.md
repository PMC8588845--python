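# Methods

`segsom` quantifies nuclear morphology and spatial organization in
brightfield histology. This note records the model, its assumptions, the
parameters that matter, the numerical choices, and what the synthetic
benchmarks do and do not establish.

## Pipeline overview

1. **Segmentation** — a tissue image is cut into overlapping 256×256 px
   tiles; a pixel classifier assigns each pixel a probability of being
   background, nucleus, or inter-nucleus boundary; tile predictions are
   blended and argmax-labelled; 4-connected components of the nucleus
   class become instances.
2. **Morphology embedding** — each nucleus becomes a 170×170 binary mask
   crop centred on its centroid, rotated so the major axis of its
   foreground pixels is horizontal, flattened row-major to a 28,900-long
   0/1 vector, and projected onto a PCA basis of dimension D = 1000.
3. **Self-organizing map** — a 7×7 hexagonal grid of prototype vectors is
   trained online for 100 epochs; every nucleus is assigned to its
   best-matching node.
4. **Taxonomy** — the 49 node prototypes are Ward-clustered and cut at six
   classes; classes are named by a size/aspect heuristic (debris,
   lymphocyte, three epithelial sizes, fibroblast) and nuclei are
   repainted with class colors (in-silico staining). Lymphocyte counts per
   image can be rank-correlated with ordinal infiltration scores.
5. **Spatial features** — per image, the 49×49 interaction matrix holds
   the mean Gaussian-kernel proximity (σ = 50 µm) between every pair of
   node classes; its 1,225-long upper triangle is reduced across images by
   NMF to 100 additive components; an L1-penalized logistic regression
   (penalty weight 0.1) selects the five largest-magnitude components; an
   L2-penalized logistic regression on those five is scored by repeated
   stratified five-fold cross-validation (precision, recall, F1, AUC per
   iteration; 5,000 iterations at full scale).
6. **IF validation** — DAPI images are registered to inverted-luminance
   H&E by cross-correlation; a perinuclear ring (3×3 dilation, 8
   iterations for epithelial classes, 5 for lymphocytes, minus the
   nucleus) samples cytoplasmic stain; per-cell means are normalized by
   the image-wide mean over cells and summarised per class with a
   rank-sum class-vs-rest test.

## Model assumptions

- Morphology is captured by the **binary mask alone**: size and shape, not
  intensity or texture. The SOM axes that emerge are size and aspect
  ratio; chromatin texture is outside this model.
- The proximity kernel treats nuclei as points (centroids in µm); σ =
  50 µm sets the scale below which two nuclei "interact".
- Interaction features are exchangeable across images: the same trained
  map (and hence the same class indexing) must be used for every image
  entering one classification.

## Key parameters

| parameter | default | units | notes |
| --- | --- | --- | --- |
| `pixel_size_um` | 0.20 | µm/px | resolution of 40× scans; every geometric quantity downstream is physical |
| `crop_size_px` | 170 | px | nuclei whose bounding box exceeds this are excluded |
| `pca_dim` (D) | 1000 | — | captures > 98% of mask variance at realistic N; clamped to min(N, 28,900) |
| `grid_rows × grid_cols` | 7 × 7 | — | 49 nodes, six neighbors for interior nodes |
| `epochs` | 100 | — | online updates, samples drawn without replacement per epoch |
| learning rate a(t) | 0.5 → 0.01 | — | linear decay per epoch |
| radius r(t) | 3.5 → 0.5 | grid steps | linear decay; Gaussian neighborhood G = exp(−g²/2r²) of the **grid** distance g to the BMU |
| `som_restarts` | 3 | — | restarts ranked by topographic error (see below) |
| `n_clusters` | 6 | — | Ward cut over node prototypes |
| `kernel_sigma_um` | 50 | µm | Gaussian proximity exp(−d²/2σ²); an unsquared variant is available as `kernel="exponential"` |
| `nmf_components` | 100 | — | clamped to min(images, 1,225) with a warning |
| `l1_weight` | 0.1 | — | penalty multiplier on Σ\|β\| (inverse strength C = 10) |
| `n_selected` | 5 | — | components kept for the final classifier |
| `cv_folds` / `cv_iterations` | 5 / 5000 | — | stratified; selection re-run inside each training fold (no leakage) |

## Numerical choices

- **Tile blending.** The blend weight d of the earlier tile ramps linearly
  from 1 at its interior edge of the overlap band to 0 at the later
  tile's interior edge; merging is separable (rows, then columns), so a
  constant map is reconstructed exactly. Argmax ties resolve by priority
  nucleus > boundary > background.
- **Alignment.** The rotation angle is the first principal component of
  the foreground pixel coordinates; rotation is nearest-neighbour (masks
  stay binary, area preserved within 2%); the 180° ambiguity is fixed by
  flipping so the third central moment of foreground x-coordinates is
  ≥ 0. The mirror ambiguity is left unresolved.
- **PCA.** Centred, not whitened. Full LAPACK SVD up to a few thousand
  samples; a seeded randomized solver only when D is well below the
  matrix rank (where it is actually faster).
- **SOM.** Prototypes initialize as seeded standard-normal vectors. BMU
  ties break to the lowest row-major node index. With a(t) ∈ [0, 1] every
  prototype coordinate provably stays inside the bounding box of data ∪
  initial prototypes. Training history records mean quantization error
  per epoch.
- **Restart selection.** Random-init online SOMs occasionally (roughly
  1 seed in 10 here) lock into a diagonally folded configuration during
  the coarse phase; such maps are identifiable without labels by their
  elevated topographic error (fraction of samples whose two best nodes
  are not adjacent) and quantization error. `train_selected` trains
  `som_restarts` maps from derived seeds and keeps the lowest-topographic-
  error one (ties: quantization error, then restart index).
- **Interaction matrix.** I(k, l) is the **mean** proximity over pairs,
  with self-pairs excluded on the diagonal; empty classes and singleton
  diagonals are 0 by convention; symmetry is enforced exactly. The
  upper triangle (not the full matrix) feeds NMF — the matrix is
  symmetric, so this loses nothing and avoids duplicated features.
- **NMF.** Deterministic SVD-based init (`nndsvda`), max 500 iterations,
  tol 1e-4, seeded.
- **Selection and CV.** Features are z-scored before both logistic fits
  (scalers fit on training folds only). Coefficient-magnitude ties break
  to the lower index; an all-zero L1 solution falls back to the first n
  indices with a warning. AUC is computed per iteration from pooled
  out-of-fold probabilities.
- **Registration.** Integer-pixel shifts only (adequate at 0.2 µm/px);
  normalized cross-correlation of mean-subtracted intensities; H&E enters
  as inverted grayscale luminance so nuclei are bright, as in DAPI.

## Synthetic data: what it emulates, what it does not

The `synthetic` module generates every benchmark dataset:

- **Single nuclei** are rotated ellipses with a 5% sinusoidal boundary
  perturbation (perfect ellipses give degenerate PCA spectra). Class
  defaults follow the lineage size brackets the naming heuristic expects:
  debris ~1.5 µm, lymphocytes ~7 µm round, epithelial ~11/14/20 µm,
  fibroblasts 24×12 µm.
- **Tissue images** place exact per-class counts without overlap
  (rejection sampling, ≥ 2 px clearance), uniformly or with class-pair
  attraction around shared cluster centers. The six-class preset uses 12
  images of 1600² px (320 µm side) with 170 nuclei each (~2,040 total).
- **The gradient preset** spans equivalent diameter 6–14 µm × aspect 1–3
  independently; these ranges give the two factors comparable shape
  variance, which is the regime in which a 7×7 map organises one axis by
  size and the other by elongation. With a much wider size range the size
  factor dominates and the aspect axis does not form.
- **Two-condition datasets** are point patterns: 8 nuclei for each of 49
  node classes, uniform in an 800 µm field; in condition B the two
  planted classes are drawn around a single shared focus (SD 10 µm) —
  one lymphoid-aggregate-like co-localization per image. A single focus
  is deliberate: it makes the planted pattern one additive part that NMF
  can isolate as a component; spreading it over several independent
  centers splits it across varying mixtures.

These fixtures have no staining variation, no texture, no segmentation
errors feeding the downstream stages, and class morphologies are tighter
than real tissue. Passing benchmarks therefore establishes the
correctness and self-consistency of the algorithms — not clinical
performance on real slides, which depends on segmentation quality and on
biological variability absent here.

## Benchmark problem sizes

Chosen so a complete run stays comfortably on one CPU: the six-class
pipeline run uses ~1,000 nuclei (tests) or ~2,040 nuclei (acceptance
script) at the full published configuration (D = 1000, 100 epochs); the
topography benchmark uses 800 gradient nuclei embedded at D = 100 (the
map consumes embeddings — the property does not depend on the embedding
dimension beyond rank sufficiency); planted-signal classification uses
40 + 40 images × 100 CV iterations × 10 repetitions, plus one 93 + 192
cohort at the realistic arm sizes for the full 100-component NMF.

## Known limitations

- The classical segmentation backend (Otsu + distance-transform
  watershed) is serviceable on high-contrast nuclei but oversplits long
  or irregular ones; a trained pixel-classifier backend plugged into the
  same 3-class contract is expected for production use.
- The class-naming heuristic is calibrated for the six-cluster default;
  other k values fall back to generic names.
- Whole-slide pyramidal formats, stain deconvolution and color
  normalization are out of scope; inputs are plain TIFF/PNG crops or
  precomputed label masks.
- Mirror symmetry of nuclei is not canonicalized, so a shape and its
  mirror image may map to different nodes.
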