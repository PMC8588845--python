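# segsom

Self-organizing-map analysis of nuclear morphology and spatial
organization in histology images.

Routine H&E slides contain far more quantitative information than a
visual read extracts: the sizes, shapes and mutual positions of cell
nuclei encode tissue composition (epithelium, stroma, immune
infiltrate) and disease state. `segsom` turns a brightfield tissue image
into that information in four steps, each usable on its own:

1. **Segment** nuclei (tile-wise 3-class pixel classification with a
   pluggable backend, or load precomputed instance masks).
2. **Embed** each nucleus: a 170×170 binary mask crop aligned to its
   major axis, flattened to a 28,900-vector and reduced by PCA to
   D = 1000 dimensions.
3. **Self-organize**: a 7×7 hexagonal Kohonen map (49 nodes) is trained
   online for 100 epochs with the update

   w(t) = w(t−1) + G(g; r(t)) · a(t) · (v − w(t−1)),

   where g is the hex-grid distance of a node to the best-matching unit,
   G = exp(−g²/2r(t)²), and a(t), r(t) decay monotonically. Ward
   clustering of the node prototypes, cut at six classes, yields named
   lineages (Debris, Lymphocyte, Epithelial1–3, Fibroblast) and an
   *in-silico stain* — every nucleus repainted by its class.
4. **Extract spatial features**: per image, the 49×49 interaction matrix
   I(k, l) = mean over nucleus pairs (i ∈ class k, j ∈ class l) of
   exp(−‖v_i − v_j‖²/2σ²), σ = 50 µm. Across images, the flattened
   matrices are reduced by NMF to 100 additive components; an
   L1-penalized logistic regression picks the five strongest components
   and an L2-penalized logistic regression on them is scored by repeated
   stratified 5-fold cross-validation (precision, recall, F1, AUC) — an
   interpretable spatial biomarker pipeline for two-group image
   classification.

A companion module validates in-silico classes against
immunofluorescence (cross-correlation registration, perinuclear-ring
stain quantification), and a first-class synthetic-data module generates
seeded tissue images, morphology gradients and planted spatial-effect
datasets so the entire pipeline is testable without any slide data.

Audience: computational pathology and tissue-biology researchers who
want interpretable, stain-free tissue statistics from standard H&E, and
methods developers who need a transparent reference implementation of
the segmentation → SOM → interaction-feature workflow.

## Worked example

```python
from segsom import synthetic, run_pipeline, PipelineConfig

# four synthetic tissue images, six morphological classes, ground truth known
tissues = synthetic.six_class_preset(n_images=4, image_size_px=1200, seed=0)
config = PipelineConfig(pca_dim=200, epochs=50, seed=0)
result = run_pipeline([inst for inst, _ in tissues], config)

print(result.class_counts())
qe = [h[1] for h in result.som_grid.history]
print(f"quantization error: {qe[0]:.2f} -> {qe[-1]:.2f}")
print(f"variance captured: {result.pca_model.explained_variance_ratio.sum():.4f}")
```

prints

```
class  Debris  Epithelial1  Epithelial2  Epithelial3  Fibroblast  Lymphocyte
image
0          25           25           15           30          20          55
1          25           25           15           30          20          55
2          25           25           15           30          20          55
3          25           25           15           30          20          55

quantization error: 21.93 -> 8.17
variance captured: 0.9854
```

Each image was generated with exactly 25 debris, 55 lymphocyte, 25 + 15
+ 30 epithelial and 20 fibroblast nuclei; the table shows the pipeline —
which never sees the labels — re-deriving that composition through the
trained map and the auto-named node clusters. The quantization error is
the mean distance of a nucleus embedding to its node prototype (falling
during training), and the PCA retains ~98.5% of mask variance even at
the reduced dimension used in this small example.

In-silico staining, lymphocyte-infiltration scoring and spatial-feature
classification continue from `result`:

```python
from segsom import taxonomy, spatial
from segsom.pipeline import image_interaction_features

img = taxonomy.render_labels(tissues[0][0], result.assignments_for_image(0),
                             result.taxonomy)        # RGB in-silico stain
feats = image_interaction_features(result)           # images × 1225
```

A thin CLI mirrors the library: `segsom segment`, `segsom som-train`,
`segsom som-assign`, `segsom features`, `segsom classify`,
`segsom synth`.

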