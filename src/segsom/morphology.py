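"""Nuclear morphology featurization.

Each segmented nucleus becomes a 170x170 binary mask crop centred on its
centroid, rotated so the major axis of its foreground pixels is horizontal,
flattened row-major to a 28,900-long 0/1 vector, and projected into a
D-dimensional PCA embedding (default D = 1000, which retains essentially
all shape variance on realistic data).  Crops are pure masks — size and
shape, not intensity, are the features the map organises.

Nuclei whose bounding box exceeds the crop size in either dimension are
excluded from the analysis.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import ndimage as ndi
from sklearn.decomposition import PCA

from .config import get_logger
from .io import InstanceSet

__all__ = ["AlignedCrop", "PCAModel", "crop_instance", "align_major_axis",
           "flatten", "unflatten", "fit_pca", "embed", "embed_instances",
           "save_pca", "load_pca", "EXCLUDED", "foreground_moments"]

logger = get_logger(__name__)

#: sentinel returned for nuclei too large for the crop window
EXCLUDED = "EXCLUDED"


@dataclasses.dataclass
class AlignedCrop:
    """A centred, major-axis-aligned binary nucleus mask."""

    mask: np.ndarray
    instance_id: int = -1
    rotation_angle: float = 0.0  # degrees applied


@dataclasses.dataclass
class PCAModel:
    """Frozen PCA basis for morphology vectors."""

    mean: np.ndarray
    components: np.ndarray  # (D, n_features), orthonormal rows
    explained_variance_ratio: np.ndarray
    dim: int


def _center_mask(mask: np.ndarray, crop_size: int) -> np.ndarray:
    """Paste a binary mask into a crop_size^2 window, centroid at the centre."""
    out = np.zeros((crop_size, crop_size), dtype=np.uint8)
    rows, cols = np.nonzero(mask)
    if len(rows) == 0:
        return out
    center = (crop_size - 1) / 2.0
    r0 = int(round(center - rows.mean()))
    c0 = int(round(center - cols.mean()))
    rr = rows + r0
    cc = cols + c0
    keep = (rr >= 0) & (rr < crop_size) & (cc >= 0) & (cc < crop_size)
    out[rr[keep], cc[keep]] = 1
    return out


def crop_instance(instance_id: int, instances: InstanceSet,
                  crop_size_px: int = 170):
    """Extract one nucleus as a centred binary crop, or ``EXCLUDED``.

    Returns the ``crop_size_px`` square mask with the nucleus centroid at
    the window centre (zero-padded near image edges), or the ``EXCLUDED``
    sentinel when the nucleus bounding box exceeds the window.
    """
    label_map = instances.label_map
    slices = ndi.find_objects((label_map == instance_id).astype(np.int8))
    if not slices or slices[0] is None:
        raise KeyError(f"instance {instance_id} not found in label map")
    sl = slices[0]
    box_h = sl[0].stop - sl[0].start
    box_w = sl[1].stop - sl[1].start
    if box_h > crop_size_px or box_w > crop_size_px:
        return EXCLUDED
    mask = (label_map[sl] == instance_id)
    return _center_mask(mask, crop_size_px)


def foreground_moments(mask: np.ndarray):
    """Centroid, principal angle (deg) and axis lengths of a binary mask.

    The angle is that of the first principal component of the foreground
    pixel coordinates, measured from the +x (column) axis; axis lengths are
    4*sqrt(eigenvalue), the full axes of the equivalent ellipse.
    """
    rows, cols = np.nonzero(mask)
    if len(rows) < 2:
        return (np.array([np.nan, np.nan]), 0.0, (0.0, 0.0))
    x = cols.astype(float)
    y = rows.astype(float)
    xc, yc = x.mean(), y.mean()
    cov = np.cov(np.stack([x - xc, y - yc]))
    evals, evecs = np.linalg.eigh(cov)  # ascending
    major = evecs[:, 1]
    angle = np.degrees(np.arctan2(major[1], major[0]))
    axes = 4.0 * np.sqrt(np.maximum(evals[::-1], 0.0))
    return (np.array([xc, yc]), angle, (axes[0], axes[1]))


def align_major_axis(crop: np.ndarray, instance_id: int = -1) -> AlignedCrop:
    """Rotate a crop so the foreground's first principal axis is horizontal.

    The per-pixel PCA runs on foreground pixel coordinates only.  Rotation
    uses nearest-neighbour resampling so the mask stays binary, the result
    is re-centred in the same window, and the 180-degree ambiguity is
    canonicalised by flipping horizontally when the third central moment of
    the foreground x-coordinates is negative.
    """
    crop = np.asarray(crop)
    size = crop.shape[0]
    n_fg = int(crop.sum())
    if n_fg < 2:
        logger.debug("instance %d has < 2 foreground pixels; skipping alignment", instance_id)
        return AlignedCrop(mask=crop.astype(np.uint8), instance_id=instance_id,
                           rotation_angle=0.0)
    _, angle, _ = foreground_moments(crop)
    # image rows grow downward, so rotating the array by -angle (scipy's
    # convention rotates counter-clockwise in array axes) brings the
    # principal axis onto the horizontal
    rotated = ndi.rotate(crop.astype(float), angle, reshape=False, order=0,
                         mode="constant", cval=0.0, prefilter=False)
    rotated = (rotated >= 0.5)
    rotated = _center_mask(rotated, size)
    cols = np.nonzero(rotated)[1].astype(float)
    if len(cols) and np.mean((cols - cols.mean()) ** 3) < 0:
        rotated = rotated[:, ::-1]
        rotated = _center_mask(rotated, size)
    return AlignedCrop(mask=rotated.astype(np.uint8), instance_id=instance_id,
                       rotation_angle=float(angle))


def flatten(crop: np.ndarray | AlignedCrop) -> np.ndarray:
    """Row-major flatten of a square binary crop into a 0/1 vector."""
    mask = crop.mask if isinstance(crop, AlignedCrop) else np.asarray(crop)
    if mask.ndim != 2 or mask.shape[0] != mask.shape[1]:
        raise ValueError(f"expected a square 2-D crop, got shape {mask.shape}")
    return mask.reshape(-1).astype(np.float64)


def unflatten(v: np.ndarray) -> np.ndarray:
    side = int(round(np.sqrt(v.size)))
    if side * side != v.size:
        raise ValueError(f"vector of length {v.size} is not a square crop")
    return np.asarray(v).reshape(side, side)


def fit_pca(vectors: np.ndarray, dim: int = 1000, seed: int = 0) -> PCAModel:
    """Fit a centred PCA basis to morphology vectors.

    ``dim`` is clamped to ``min(n_samples, n_features)`` with a warning.
    A randomized solver is used when the problem is large, the exact solver
    otherwise; either way the result is reproducible given ``seed``.
    """
    X = np.asarray(vectors, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need an (N >= 2) x n_features matrix")
    max_dim = min(X.shape)
    if dim > max_dim:
        warnings.warn(f"pca dim {dim} clamped to {max_dim}")
        dim = max_dim
    # randomized SVD only pays off when dim is well below the matrix rank
    solver = ("randomized"
              if (X.shape[0] * X.shape[1] > 5_000_000 and dim < 0.5 * max_dim)
              else "full")
    pca = PCA(n_components=dim, svd_solver=solver, random_state=seed)
    pca.fit(X)
    return PCAModel(mean=pca.mean_, components=pca.components_,
                    explained_variance_ratio=pca.explained_variance_ratio_, dim=dim)


def save_pca(path, model: PCAModel) -> None:
    """Serialize a PCA basis to an .npz archive with a JSON header."""
    import json

    header = json.dumps({"dim": model.dim, "n_features": model.components.shape[1]})
    np.savez(path, mean=model.mean, components=model.components,
             explained_variance_ratio=model.explained_variance_ratio,
             header=np.frombuffer(header.encode(), dtype=np.uint8))


def load_pca(path) -> PCAModel:
    import json

    with np.load(path) as data:
        meta = json.loads(bytes(data["header"]).decode())
        return PCAModel(mean=data["mean"].copy(), components=data["components"].copy(),
                        explained_variance_ratio=data["explained_variance_ratio"].copy(),
                        dim=meta["dim"])


def embed(model: PCAModel, vectors: np.ndarray) -> np.ndarray:
    """Project vectors (one per row, or a single vector) onto the PCA basis."""
    V = np.atleast_2d(np.asarray(vectors, dtype=np.float64))
    emb = (V - model.mean) @ model.components.T
    return emb[0] if np.asarray(vectors).ndim == 1 else emb


def embed_instances(instances: InstanceSet, crop_size_px: int = 170,
                    pca_dim: int = 1000, seed: int = 0):
    """Crop, align and embed every instance of an :class:`InstanceSet`.

    Returns ``(embeddings, kept_labels, crops, model)`` where ``kept_labels``
    lists the instance ids that were not excluded for size.
    """
    crops = []
    kept = []
    for lab in instances.labels:
        crop = crop_instance(int(lab), instances, crop_size_px)
        if crop is EXCLUDED:
            logger.info("instance %d larger than %d px crop; excluded", lab, crop_size_px)
            continue
        crops.append(align_major_axis(crop, instance_id=int(lab)))
        kept.append(int(lab))
    if not crops:
        raise ValueError("no instances small enough to embed")
    X = np.stack([flatten(c) for c in crops])
    model = fit_pca(X, dim=pca_dim, seed=seed)
    return embed(model, X), np.asarray(kept), crops, model
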