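"""From SOM nodes to named cell classes and in-silico staining.

The trained node prototypes are hierarchically clustered (Ward linkage, cut
at six clusters by default), each cluster is named by a size/aspect
heuristic that formalises the morphological ranges of the major tissue
lineages (debris < 2 um; lymphocytes 2-10 um and nearly circular;
fibroblasts elongated; three epithelial classes by increasing size), and
segmented nuclei are repainted with their class color — an in-silico stain
of the tissue.  Lymphocyte counts per image can be compared with ordinal
pathologist infiltration scores by Spearman rank correlation.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import spearmanr

from .config import get_logger
from .io import InstanceSet

__all__ = ["NodeTaxonomy", "ClassStats", "cluster_nodes", "node_stats",
           "annotate_classes", "render_labels", "count_class",
           "lymphocyte_report", "save_taxonomy", "load_taxonomy",
           "DEFAULT_PALETTE", "CLASS_NAMES"]

logger = get_logger(__name__)

CLASS_NAMES = ("Debris", "Lymphocyte", "Epithelial1", "Epithelial2",
               "Epithelial3", "Fibroblast")

#: in-silico stain colors (RGB), one per canonical class name
DEFAULT_PALETTE = {
    "Debris": (240, 210, 40),       # yellow
    "Lymphocyte": (60, 210, 210),   # cyan
    "Epithelial1": (50, 80, 220),   # blue
    "Epithelial2": (240, 130, 200), # pink
    "Epithelial3": (220, 40, 40),   # red
    "Fibroblast": (60, 180, 60),    # green
}
BACKGROUND_COLOR = (255, 255, 255)


@dataclasses.dataclass
class NodeTaxonomy:
    """Ward linkage tree over node vectors plus a class id/name per node."""

    linkage_matrix: np.ndarray
    class_ids: np.ndarray      # 1..k per node
    n_classes: int
    class_names: dict = None   # class id -> name
    palette: dict = None       # class id -> RGB

    def __post_init__(self) -> None:
        if self.class_names is None:
            self.class_names = {k: f"class_{k}" for k in range(1, self.n_classes + 1)}
        if self.palette is None:
            import matplotlib

            cmap = matplotlib.colormaps["tab10"]
            self.palette = {k: tuple(int(255 * c) for c in cmap((k - 1) % 10)[:3])
                            for k in range(1, self.n_classes + 1)}

    def name_of_node(self, node: int) -> str:
        return self.class_names[int(self.class_ids[node])]


@dataclasses.dataclass
class ClassStats:
    """Per-node morphology summaries of the nuclei assigned to each node."""

    mean_equivalent_diameter_um: np.ndarray  # per node, nan if empty
    mean_aspect_ratio: np.ndarray            # per node, nan if empty
    n_assigned: np.ndarray                   # per node


def save_taxonomy(path, taxonomy: NodeTaxonomy) -> None:
    """Write a taxonomy (linkage, class ids, names, palette) as JSON."""
    import json
    from pathlib import Path

    Path(path).write_text(json.dumps({
        "linkage_matrix": taxonomy.linkage_matrix.tolist(),
        "class_ids": taxonomy.class_ids.tolist(),
        "n_classes": taxonomy.n_classes,
        "class_names": {str(k): v for k, v in taxonomy.class_names.items()},
        "palette": {str(k): list(v) for k, v in taxonomy.palette.items()},
    }, indent=2) + "\n")


def load_taxonomy(path) -> NodeTaxonomy:
    import json
    from pathlib import Path

    data = json.loads(Path(path).read_text())
    return NodeTaxonomy(
        linkage_matrix=np.asarray(data["linkage_matrix"], dtype=float),
        class_ids=np.asarray(data["class_ids"], dtype=int),
        n_classes=int(data["n_classes"]),
        class_names={int(k): v for k, v in data["class_names"].items()},
        palette={int(k): tuple(v) for k, v in data["palette"].items()})


def cluster_nodes(W: np.ndarray, k: int = 6) -> NodeTaxonomy:
    """Ward-linkage agglomerative clustering of node vectors, cut at ``k``."""
    W = np.asarray(W, dtype=float)
    if k > W.shape[0]:
        raise ValueError(f"cannot cut {W.shape[0]} nodes into {k} clusters")
    Z = linkage(W, method="ward")
    ids = fcluster(Z, t=k, criterion="maxclust")
    return NodeTaxonomy(linkage_matrix=Z, class_ids=np.asarray(ids), n_classes=k)


def node_stats(crops, assignments: np.ndarray, n_nodes: int,
               pixel_size: float) -> ClassStats:
    """Morphology summaries per node from aligned crops and BMU assignments.

    Equivalent diameter of a mask is ``2 * sqrt(area / pi) * pixel_size``;
    aspect ratio is the major/minor axis ratio of the foreground second
    moments (>= 1).
    """
    from .morphology import AlignedCrop, foreground_moments

    diam = np.full(n_nodes, np.nan)
    aspect = np.full(n_nodes, np.nan)
    counts = np.zeros(n_nodes, dtype=int)
    areas = np.zeros(len(crops))
    aspects = np.ones(len(crops))
    for i, crop in enumerate(crops):
        mask = crop.mask if isinstance(crop, AlignedCrop) else np.asarray(crop)
        areas[i] = mask.sum()
        _, _, (major, minor) = foreground_moments(mask)
        aspects[i] = major / minor if minor > 0 else 1.0
    eq_diam = 2.0 * np.sqrt(areas / np.pi) * pixel_size
    for node in range(n_nodes):
        sel = assignments == node
        counts[node] = sel.sum()
        if counts[node]:
            diam[node] = eq_diam[sel].mean()
            aspect[node] = np.maximum(aspects[sel], 1.0).mean()
    return ClassStats(mean_equivalent_diameter_um=diam, mean_aspect_ratio=aspect,
                      n_assigned=counts)


def annotate_classes(taxonomy: NodeTaxonomy, stats: ClassStats,
                     name_map: dict | None = None) -> NodeTaxonomy:
    """Attach lineage names to the clusters of a 6-class taxonomy.

    The heuristic formalises the published morphological ranges: clusters
    are summarised by the (assignment-weighted) mean equivalent diameter
    and aspect ratio of their nuclei, then named in rule order —

    1. mean diameter < 2 um  -> Debris
    2. highest mean aspect ratio of the rest -> Fibroblast
    3. smallest remaining cluster, if 2-10 um and aspect < 1.5 -> Lymphocyte
    4. remaining three, ascending diameter -> Epithelial3, Epithelial1,
       Epithelial2 (roughly 10-12, 10-15 and 15-25 um).

    Collisions fall back to rank order by diameter.  For k != 6 the generic
    ``class_k`` names are kept.  An explicit ``name_map`` (class id -> name)
    overrides the heuristic entirely.
    """
    tax = dataclasses.replace(taxonomy)
    if name_map is not None:
        tax.class_names = dict(name_map)
        tax.palette = {k: DEFAULT_PALETTE.get(v, (128, 128, 128))
                       for k, v in tax.class_names.items()}
        return tax
    k = taxonomy.n_classes
    if k != 6:
        logger.warning("lineage annotation is defined for 6 classes, got %d; "
                       "keeping generic names", k)
        return tax

    # cluster summaries, weighted by how many nuclei each node attracted
    cl_diam = np.zeros(k)
    cl_aspect = np.zeros(k)
    for ci in range(1, k + 1):
        nodes = np.flatnonzero(taxonomy.class_ids == ci)
        wts = stats.n_assigned[nodes].astype(float)
        d = stats.mean_equivalent_diameter_um[nodes]
        a = stats.mean_aspect_ratio[nodes]
        ok = np.isfinite(d) & (wts > 0)
        if ok.any():
            cl_diam[ci - 1] = np.average(d[ok], weights=wts[ok])
            cl_aspect[ci - 1] = np.average(a[ok], weights=wts[ok])
        else:
            cl_diam[ci - 1] = np.nan
            cl_aspect[ci - 1] = np.nan

    order = np.argsort(np.where(np.isfinite(cl_diam), cl_diam, np.inf))
    names = {}
    remaining = [int(c) for c in order]  # ascending diameter

    if all(cl_diam[c] < 2.0 for c in remaining if np.isfinite(cl_diam[c])):
        warnings.warn("all clusters have mean diameter < 2 um; Debris-ranked names")

    # 1. Debris: smallest cluster when < 2 um
    if remaining and np.isfinite(cl_diam[remaining[0]]) and cl_diam[remaining[0]] < 2.0:
        names[remaining.pop(0) + 1] = "Debris"
    # 2. Fibroblast: highest aspect ratio of the rest
    if remaining:
        fib = max(remaining, key=lambda c: (cl_aspect[c] if np.isfinite(cl_aspect[c]) else -1))
        remaining.remove(fib)
        names[fib + 1] = "Fibroblast"
    # 3. Lymphocyte: smallest remaining (small round, 2-10 um)
    if remaining:
        lym = remaining.pop(0)
        names[lym + 1] = "Lymphocyte"
        if not (2.0 <= cl_diam[lym] <= 10.0 and cl_aspect[lym] < 1.5):
            logger.warning("Lymphocyte-named cluster (%.1f um, aspect %.2f) is outside "
                           "the 2-10 um round range", cl_diam[lym], cl_aspect[lym])
    # 4. remaining three ascending: Epithelial3 < Epithelial1 < Epithelial2
    for name in ("Epithelial3", "Epithelial1", "Epithelial2"):
        if remaining:
            names[remaining.pop(0) + 1] = name
    # any clusters left (degenerate k): rank-ordered fallback names
    for i, c in enumerate(remaining):
        names[c + 1] = f"class_{c + 1}"

    tax.class_names = names
    tax.palette = {cid: DEFAULT_PALETTE.get(nm, (128, 128, 128))
                   for cid, nm in names.items()}
    return tax


def render_labels(instances: InstanceSet, node_assignments: dict,
                  taxonomy: NodeTaxonomy, canvas: np.ndarray | None = None) -> np.ndarray:
    """Paint every nucleus with its class color — the in-silico stain.

    ``node_assignments`` maps instance id -> SOM node index.  Unassigned
    instances are an error; the background stays white.
    """
    label_map = instances.label_map
    missing = [int(lab) for lab in instances.labels if int(lab) not in node_assignments]
    if missing:
        raise ValueError(f"instances without node assignment: {missing}")
    if canvas is None:
        canvas = np.full((*label_map.shape, 3), 255, dtype=np.uint8)
    lut = np.zeros((int(label_map.max()) + 1, 3), dtype=np.uint8)
    lut[0] = BACKGROUND_COLOR
    for lab in instances.labels:
        cid = int(taxonomy.class_ids[node_assignments[int(lab)]])
        lut[int(lab)] = taxonomy.palette[cid]
    fg = label_map > 0
    canvas[fg] = lut[label_map[fg]]
    return canvas


def count_class(node_assignments, taxonomy: NodeTaxonomy, class_name: str) -> int:
    """Number of nuclei whose node belongs to the named class."""
    nodes = np.asarray(list(node_assignments.values())
                       if isinstance(node_assignments, dict) else node_assignments)
    names = np.array([taxonomy.name_of_node(n) for n in nodes])
    return int(np.sum(names == class_name))


def lymphocyte_report(counts, scores):
    """Rank-correlate per-image lymphocyte counts with infiltration scores.

    Returns ``(rho, p_value, table)`` where the table lists per-image count,
    log2(count + 1) and score.  Scores are ordinal (e.g. 1-3 pathologist
    immunoscore); ties are handled by the rank correlation itself.
    """
    counts = np.asarray(counts, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if counts.size == 0:
        raise ValueError("empty image set")
    if counts.shape != scores.shape:
        raise ValueError("counts and scores must align")
    rho, p = spearmanr(counts, scores)
    import pandas as pd

    table = pd.DataFrame({"count": counts, "log2_count": np.log2(counts + 1.0),
                          "score": scores})
    return float(rho), float(p), table
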