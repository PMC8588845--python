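"""Seeded synthetic fixtures for every pipeline stage.

Three generators:

* single nuclei — rotated, boundary-jittered ellipse masks parameterised in
  micrometres, one per :class:`NucleusSpec`;
* tissue images — non-overlapping nuclei of the six morphological classes
  placed uniformly or with controllable class-pair attraction, with ground
  truth instance labels and classes;
* two-condition datasets — point patterns over SOM node classes in which
  one designated node pair is drawn closer together in condition B (a
  planted spatial-interaction effect), for end-to-end classifier tests.

Class morphology defaults follow the lineage size brackets the taxonomy
heuristic expects: debris ~1.5 um, lymphocytes ~7 um round, epithelial
classes ~11/14/20 um, fibroblasts elongated 12 x 24 um.

All outputs are deterministic functions of (spec, seed).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .config import DEFAULT_PIXEL_SIZE_UM, child_rng
from .io import InstanceSet

__all__ = ["NucleusSpec", "TissueSpec", "CLASS_SHAPES_UM", "gen_nucleus",
           "gen_tissue", "gen_two_condition_dataset", "gradient_nuclei_preset",
           "six_class_preset", "render_tissue_image",
           "DEFAULT_CLASS_COUNTS"]

#: default (major, minor) ellipse axes in micrometres per morphological class
CLASS_SHAPES_UM = {
    "Debris": (1.5, 1.4),
    "Lymphocyte": (7.5, 6.5),
    "Epithelial3": (11.5, 10.5),
    "Epithelial1": (14.5, 13.2),
    "Epithelial2": (20.0, 18.0),
    "Fibroblast": (24.0, 12.0),
}

#: per-image class mix of the six-class tissue preset
DEFAULT_CLASS_COUNTS = {
    "Debris": 25, "Lymphocyte": 55, "Epithelial1": 25,
    "Epithelial2": 15, "Epithelial3": 30, "Fibroblast": 20,
}


@dataclasses.dataclass
class NucleusSpec:
    """One elliptical nucleus in physical units."""

    major_um: float
    minor_um: float
    orientation_deg: float = 0.0
    class_label: str = "other"
    jitter_amp: float = 0.05      # fractional sinusoidal boundary perturbation
    jitter_lobes: int = 5
    jitter_phase: float = 0.0

    def __post_init__(self) -> None:
        if not (self.major_um >= self.minor_um > 0):
            raise ValueError("need major >= minor > 0")


@dataclasses.dataclass
class TissueSpec:
    """One synthetic tissue image: class counts, layout, physical size."""

    image_size_px: int = 1024
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    class_counts: dict = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_CLASS_COUNTS))
    layout: str = "uniform"          # or "clustered"
    attraction: dict = dataclasses.field(default_factory=dict)
    # class-pair -> cluster spread (um); smaller = tighter co-localization
    n_cluster_centers: int = 3
    min_gap_px: int = 2
    size_jitter: float = 0.08        # fractional sd-free uniform half-range
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.class_counts.values()):
            raise ValueError("class counts must be >= 0")
        if self.layout not in ("uniform", "clustered"):
            raise ValueError(f"unknown layout {self.layout!r}")


def gen_nucleus(spec: NucleusSpec, pixel_size: float = DEFAULT_PIXEL_SIZE_UM) -> np.ndarray:
    """Render one nucleus as a binary mask on a minimal canvas.

    The boundary radius is modulated by ``1 + amp * sin(lobes * phi + phase)``
    so masks are not perfect ellipses (degenerate PCA spectra otherwise);
    with the default 5% amplitude the area stays within 5% of the analytic
    ellipse area for axes of at least 4 px.
    """
    ra = spec.major_um / 2.0 / pixel_size
    rb = spec.minor_um / 2.0 / pixel_size
    if 2 * rb < 1.0:
        raise ValueError(f"minor axis {spec.minor_um} um is below 1 px at "
                         f"{pixel_size} um/px")
    half = int(np.ceil(max(ra, rb) * (1.0 + spec.jitter_amp))) + 1
    yy, xx = np.mgrid[-half:half + 1, -half:half + 1].astype(float)
    theta = np.radians(spec.orientation_deg)
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    # snap near-zero terms so quarter-turn rotations are exact on the grid
    cos_t = 0.0 if abs(cos_t) < 1e-12 else cos_t
    sin_t = 0.0 if abs(sin_t) < 1e-12 else sin_t
    # rotate coordinates into the ellipse frame (x = col, y = row, y down)
    xr = xx * cos_t + yy * sin_t
    yr = -xx * sin_t + yy * cos_t
    u = xr / ra
    v = yr / rb
    phi = np.arctan2(v, u)
    s = 1.0 + spec.jitter_amp * np.sin(spec.jitter_lobes * phi + spec.jitter_phase)
    return ((u * u + v * v) <= s * s).astype(np.uint8)


def _random_spec(class_label: str, rng: np.random.Generator,
                 size_jitter: float) -> NucleusSpec:
    major, minor = CLASS_SHAPES_UM[class_label]
    scale = 1.0 + rng.uniform(-size_jitter, size_jitter)
    return NucleusSpec(major_um=major * scale, minor_um=minor * scale,
                       orientation_deg=rng.uniform(0.0, 180.0),
                       class_label=class_label,
                       jitter_phase=rng.uniform(0.0, 2.0 * np.pi))


def gen_tissue(spec: TissueSpec):
    """Place the requested nuclei without overlap; return ground truth.

    Returns ``(instances, classes)``: an :class:`InstanceSet` whose label
    map holds instance k at label k, and the generating class name per
    instance (aligned with labels 1..N).  Placement is rejection sampling
    with a ``min_gap_px`` clearance; an error suggests a larger canvas when
    packing fails.
    """
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size_px
    occupancy = np.zeros((size, size), dtype=bool)
    label_map = np.zeros((size, size), dtype=np.int32)

    nuclei = []
    for cls, count in spec.class_counts.items():
        nuclei.extend(_random_spec(cls, rng, spec.size_jitter) for _ in range(count))
    # large first packs better; shuffle within equal sizes via stable key
    areas = [n.major_um * n.minor_um for n in nuclei]
    order = np.argsort(-np.asarray(areas), kind="stable")
    nuclei = [nuclei[i] for i in order]

    centers_of_pair = {}
    if spec.layout == "clustered":
        for pair, sd in spec.attraction.items():
            key = frozenset(pair)
            centers_of_pair[key] = rng.uniform(0, size * spec.pixel_size_um,
                                               size=(spec.n_cluster_centers, 2))
    attracted = set()
    for pair in spec.attraction:
        attracted |= set(pair)

    from scipy import ndimage as ndi

    classes = []
    lab = 0
    for nucleus in nuclei:
        mask = gen_nucleus(nucleus, spec.pixel_size_um)
        if spec.min_gap_px:
            footprint = ndi.binary_dilation(mask, iterations=spec.min_gap_px)
        else:
            footprint = mask.astype(bool)
        h, w = mask.shape
        placed = False
        for _ in range(300):
            if spec.layout == "clustered" and nucleus.class_label in attracted:
                key = next(k for k in centers_of_pair if nucleus.class_label in k)
                sd = spec.attraction[next(p for p in spec.attraction
                                          if frozenset(p) == key)]
                center_um = centers_of_pair[key][rng.integers(len(centers_of_pair[key]))]
                pos_um = center_um + rng.normal(0.0, sd, size=2)
                c = int(round(pos_um[0] / spec.pixel_size_um)) - w // 2
                r = int(round(pos_um[1] / spec.pixel_size_um)) - h // 2
            else:
                r = int(rng.integers(0, size - h)) if size > h else 0
                c = int(rng.integers(0, size - w)) if size > w else 0
            if r < 0 or c < 0 or r + h > size or c + w > size:
                continue
            region = occupancy[r:r + h, c:c + w]
            if not (region & footprint).any():
                occupancy[r:r + h, c:c + w] |= footprint
                lab += 1
                patch = label_map[r:r + h, c:c + w]
                patch[mask.astype(bool)] = lab
                classes.append(nucleus.class_label)
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place a {nucleus.class_label} nucleus after 300 tries; "
                "reduce counts or enlarge image_size_px")
    instances = InstanceSet(label_map=label_map, pixel_size=spec.pixel_size_um)
    return instances, classes


def render_tissue_image(instances: InstanceSet, background: int = 245,
                        foreground: int = 60, noise_sd: float = 0.0,
                        seed: int = 0) -> np.ndarray:
    """Grayscale brightfield-like rendering: dark nuclei on a light field."""
    img = np.full(instances.label_map.shape, float(background))
    img[instances.label_map > 0] = float(foreground)
    if noise_sd > 0:
        img += np.random.default_rng(seed).normal(0.0, noise_sd, img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def gradient_nuclei_preset(n: int = 1000, seed: int = 0,
                           diameter_range_um=(6.0, 14.0),
                           aspect_range=(1.0, 3.0),
                           pixel_size: float = DEFAULT_PIXEL_SIZE_UM):
    """Nuclei spanning a 2-D size x aspect gradient, for topography tests.

    Returns ``(masks, areas_um2, aspects)`` where size and elongation vary
    independently and uniformly across the set.  The default ranges
    (equivalent diameter 6-14 um, aspect 1-3) give the two factors
    comparable shape-variance contributions, so a trained map organises one
    grid axis by size and the other by elongation.
    """
    rng = np.random.default_rng(seed)
    masks, areas, aspects = [], [], []
    for _ in range(n):
        eq_diam = rng.uniform(*diameter_range_um)
        aspect = rng.uniform(*aspect_range)
        # keep the ellipse area equal to the equivalent-diameter disc area
        minor = eq_diam / np.sqrt(aspect)
        major = eq_diam * np.sqrt(aspect)
        spec = NucleusSpec(major_um=major, minor_um=minor,
                           orientation_deg=rng.uniform(0, 180),
                           jitter_phase=rng.uniform(0, 2 * np.pi))
        masks.append(gen_nucleus(spec, pixel_size))
        areas.append(np.pi * (eq_diam / 2.0) ** 2)
        aspects.append(aspect)
    return masks, np.asarray(areas), np.asarray(aspects)


def six_class_preset(n_images: int = 12, image_size_px: int = 1600,
                     class_counts: dict | None = None, seed: int = 0,
                     pixel_size: float = DEFAULT_PIXEL_SIZE_UM):
    """The default six-class tissue dataset (~2000 nuclei at full scale).

    Returns a list of ``(InstanceSet, classes)`` tuples, one per image.
    """
    counts = dict(DEFAULT_CLASS_COUNTS if class_counts is None else class_counts)
    out = []
    for i in range(n_images):
        spec = TissueSpec(image_size_px=image_size_px, pixel_size_um=pixel_size,
                          class_counts=counts,
                          seed=int(child_rng(seed, f"tissue-{i}").integers(2**31)))
        out.append(gen_tissue(spec))
    return out


def gen_two_condition_dataset(n_per_arm=(40, 40), n_nodes: int = 49,
                              planted_pair=(10, 30), effect: float = 1.0,
                              n_per_class: int = 8, field_um: float = 800.0,
                              cluster_sd_um: float = 10.0,
                              n_cluster_centers: int = 1, seed: int = 0):
    """Point-pattern dataset with a planted class-pair proximity effect.

    Each "image" is a set of nucleus centroids (um) with a SOM node class
    per nucleus (``n_per_class`` nuclei for each of ``n_nodes`` classes,
    uniform in a ``field_um`` square).  In condition B (label 1) each
    nucleus of the two planted classes is, with probability ``effect``,
    drawn near one of ``n_cluster_centers`` shared cluster centers
    (Gaussian spread ``cluster_sd_um``), raising their mutual proximity;
    ``effect = 0`` is the exchangeable null.  The default single center
    emulates one lymphoid-aggregate-like focus of co-localization per
    image.  Arm sizes default to scaled-down equal arms; pass ``(93, 192)``
    to mirror a realistically imbalanced cohort.

    Returns ``(images, labels)``: a list of dicts with keys ``centroids``
    and ``nodes``, and the 0/1 condition labels.
    """
    if min(n_per_arm) < 2:
        raise ValueError("need at least 2 images per arm")
    if not 0.0 <= effect <= 1.0:
        raise ValueError("effect must lie in [0, 1]")
    k, l = planted_pair
    if not (0 <= k < n_nodes and 0 <= l < n_nodes):
        raise ValueError("planted pair must be valid node classes")
    rng = np.random.default_rng(seed)
    images, labels = [], []
    for arm, n_images in enumerate(n_per_arm):
        for _ in range(n_images):
            nodes = np.repeat(np.arange(n_nodes), n_per_class)
            pos = rng.uniform(0.0, field_um, size=(nodes.size, 2))
            if arm == 1 and effect > 0:
                centers = rng.uniform(0.0, field_um, size=(n_cluster_centers, 2))
                planted = np.isin(nodes, [k, l])
                move = planted & (rng.random(nodes.size) < effect)
                idx = np.flatnonzero(move)
                chosen = centers[rng.integers(n_cluster_centers, size=idx.size)]
                pos[idx] = np.clip(chosen + rng.normal(0, cluster_sd_um,
                                                       size=(idx.size, 2)),
                                   0.0, field_um)
            images.append({"centroids": pos, "nodes": nodes})
            labels.append(arm)
    return images, np.asarray(labels, dtype=int)
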