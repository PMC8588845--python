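"""End-to-end orchestration: instances -> embeddings -> SOM -> taxonomy.

The entry point is :func:`run_pipeline`, which takes segmented instance
sets (one per image, from the segmentation module or from pre-computed
label masks) and a :class:`~segsom.config.PipelineConfig`, and returns the
trained map, the annotated taxonomy and per-image node assignments — the
inputs both the in-silico staining and the spatial-feature stages consume.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import morphology, som, taxonomy
from .config import PipelineConfig, child_seed, get_logger, stage_timer
from .io import InstanceSet

__all__ = ["PipelineResult", "run_pipeline", "image_interaction_features"]

logger = get_logger(__name__)


@dataclasses.dataclass
class PipelineResult:
    """Everything the downstream stages need from one trained run."""

    config: PipelineConfig
    pca_model: morphology.PCAModel
    som_grid: som.SOMGrid
    taxonomy: taxonomy.NodeTaxonomy
    stats: taxonomy.ClassStats
    embeddings: np.ndarray          # all kept nuclei, dataset order
    crops: list                     # AlignedCrop per kept nucleus
    image_index: np.ndarray         # image id per kept nucleus
    instance_labels: np.ndarray     # instance label per kept nucleus
    node_assignments: np.ndarray    # BMU node per kept nucleus
    instance_sets: list

    def assignments_for_image(self, image_id: int) -> dict:
        """instance label -> node index, for one image."""
        sel = self.image_index == image_id
        return {int(lab): int(node) for lab, node in
                zip(self.instance_labels[sel], self.node_assignments[sel])}

    def centroids_for_image(self, image_id: int):
        """(centroids_um, node_assignments) of the kept nuclei of one image."""
        inst = self.instance_sets[image_id]
        sel = self.image_index == image_id
        labels = self.instance_labels[sel]
        cent = np.stack([inst.centroid_of(int(lab)) for lab in labels])
        return cent, self.node_assignments[sel]

    def class_counts(self) -> pd.DataFrame:
        """Per-image count of nuclei in each named class."""
        names = np.array([self.taxonomy.name_of_node(n) for n in self.node_assignments])
        df = pd.DataFrame({"image": self.image_index, "class": names})
        return df.groupby(["image", "class"]).size().unstack(fill_value=0)

    def to_embedding_table(self) -> pd.DataFrame:
        cols = {f"pc{j + 1}": self.embeddings[:, j]
                for j in range(self.embeddings.shape[1])}
        fg = [int(c.mask.sum()) for c in self.crops]
        return pd.DataFrame({"image": self.image_index,
                             "instance": self.instance_labels,
                             "foreground_px": fg, **cols})


def run_pipeline(instance_sets: list[InstanceSet],
                 config: PipelineConfig | None = None) -> PipelineResult:
    """Crop, align, embed, train the SOM and build the named taxonomy."""
    config = config or PipelineConfig()
    crops = []
    image_index = []
    instance_labels = []
    with stage_timer("morphology: crop + align", logger):
        for img_id, inst in enumerate(instance_sets):
            for lab in inst.labels:
                crop = morphology.crop_instance(int(lab), inst, config.crop_size_px)
                if crop is morphology.EXCLUDED:
                    logger.info("image %d instance %d excluded (too large)", img_id, lab)
                    continue
                crops.append(morphology.align_major_axis(crop, instance_id=int(lab)))
                image_index.append(img_id)
                instance_labels.append(int(lab))
    if not crops:
        raise ValueError("no nuclei to analyse")
    X = np.stack([morphology.flatten(c) for c in crops])

    with stage_timer("morphology: PCA embedding", logger):
        pca_model = morphology.fit_pca(X, dim=config.pca_dim,
                                       seed=child_seed(config.seed, "pca"))
        emb = morphology.embed(pca_model, X)

    with stage_timer("som: training", logger):
        schedule = som.TrainSchedule.for_grid(config.grid_rows, config.grid_cols,
                                              epochs=config.epochs)
        grid = som.train_selected(config.grid_rows, config.grid_cols, emb,
                                  schedule, seed=child_seed(config.seed, "som"),
                                  n_restarts=config.som_restarts)
        assignments = som.assign_all(grid, emb)

    with stage_timer("taxonomy: clustering + annotation", logger):
        pixel_size = instance_sets[0].pixel_size
        tax = taxonomy.cluster_nodes(grid.W, k=config.n_clusters)
        stats = taxonomy.node_stats(crops, assignments, grid.hex.n_nodes, pixel_size)
        tax = taxonomy.annotate_classes(tax, stats)

    return PipelineResult(config=config, pca_model=pca_model, som_grid=grid,
                          taxonomy=tax, stats=stats, embeddings=emb, crops=crops,
                          image_index=np.asarray(image_index),
                          instance_labels=np.asarray(instance_labels),
                          node_assignments=assignments,
                          instance_sets=list(instance_sets))


def image_interaction_features(result: PipelineResult):
    """Per-image flattened interaction-matrix features from a trained run."""
    from . import spatial

    kernel = spatial.ProximityKernel(sigma=result.config.kernel_sigma_um,
                                     form=result.config.kernel)
    n_nodes = result.som_grid.hex.n_nodes
    rows = []
    for img_id in range(len(result.instance_sets)):
        cent, nodes = result.centroids_for_image(img_id)
        I = spatial.interaction_matrix(cent, nodes, kernel, n_nodes)
        rows.append(spatial.flatten_interactions(I))
    return np.stack(rows)
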