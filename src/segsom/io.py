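"""Image and label-map I/O with physical pixel-size metadata.

Coordinate convention: arrays are indexed ``(row, col)``; exported positions
are ``(x, y)`` in micrometres with ``x = col * pixel_size`` and
``y = row * pixel_size``.  All downstream geometry is in micrometres.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import imageio.v3 as iio
import tifffile

from .config import DEFAULT_PIXEL_SIZE_UM

__all__ = ["TissueImage", "InstanceSet", "read_image", "write_image",
           "read_label_map", "write_label_map", "instances_from_label_map"]

CHANNEL_ROLES = ("HE", "DAPI", "CD3", "KER", "other")


@dataclasses.dataclass
class TissueImage:
    """A brightfield (H&W&3) or single-channel fluorescence (H&W) image."""

    pixels: np.ndarray
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    channel_role: str = "HE"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (2, 3):
            raise ValueError(f"expected 2-D or 3-D pixel array, got shape {self.pixels.shape}")
        if self.pixels.ndim == 3 and self.pixels.shape[2] != 3:
            raise ValueError(f"3-D images must have 3 channels, got {self.pixels.shape[2]}")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must be at least 1x1")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.channel_role not in CHANNEL_ROLES:
            raise ValueError(f"channel_role must be one of {CHANNEL_ROLES}")
        if np.issubdtype(self.pixels.dtype, np.floating) and not np.all(np.isfinite(self.pixels)):
            raise ValueError("image intensities must be finite")

    @property
    def shape(self) -> tuple:
        return self.pixels.shape


@dataclasses.dataclass
class InstanceSet:
    """An integer instance label map plus per-instance centroids in um.

    ``label_map`` holds 0 for background and k >= 1 for instance k.
    ``labels`` lists the instance ids present (sorted); ``centroids`` is an
    ``(N, 2)`` array of ``(x, y)`` positions in micrometres, aligned with
    ``labels``.
    """

    label_map: np.ndarray
    pixel_size: float
    labels: np.ndarray = None
    centroids: np.ndarray = None

    def __post_init__(self) -> None:
        self.label_map = np.asarray(self.label_map)
        if self.label_map.ndim != 2:
            raise ValueError("label_map must be 2-D")
        if not np.issubdtype(self.label_map.dtype, np.integer):
            raise ValueError("label_map must be integer-valued")
        if self.label_map.size and self.label_map.min() < 0:
            raise ValueError("negative labels are not allowed")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.labels is None:
            self.labels, self.centroids = _centroids_um(self.label_map, self.pixel_size)
        else:
            self.labels = np.asarray(self.labels)
            self.centroids = np.asarray(self.centroids, dtype=float)

    @property
    def n_instances(self) -> int:
        return len(self.labels)

    def centroid_of(self, label: int) -> np.ndarray:
        idx = np.flatnonzero(self.labels == label)
        if len(idx) == 0:
            raise KeyError(f"instance {label} not present")
        return self.centroids[idx[0]]


def _centroids_um(label_map: np.ndarray, pixel_size: float):
    labels = np.unique(label_map)
    labels = labels[labels > 0]
    if len(labels) == 0:
        return labels, np.zeros((0, 2))
    from scipy import ndimage as ndi

    cent_rc = ndi.center_of_mass(np.ones_like(label_map), label_map, labels)
    cent_rc = np.atleast_2d(np.asarray(cent_rc, dtype=float))
    # (x, y) um = (col, row) px * pixel_size
    centroids = np.column_stack([cent_rc[:, 1], cent_rc[:, 0]]) * pixel_size
    return labels, centroids


def read_image(path: str | Path, pixel_size: float | None = None,
               channel_role: str = "HE") -> TissueImage:
    """Read a TIFF/PNG image into a :class:`TissueImage`.

    ``pixel_size`` falls back to the 0.20 um/px default of the 40x scans.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            pixels = tifffile.imread(path)
        else:
            pixels = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend specific
        raise IOError(f"could not read image {path}: {exc}") from exc
    if pixels.ndim == 3 and pixels.shape[2] == 4:  # drop alpha
        pixels = pixels[:, :, :3]
    if pixels.ndim not in (2, 3) or (pixels.ndim == 3 and pixels.shape[2] != 3):
        raise ValueError(f"unsupported image layout {pixels.shape} in {path}")
    if channel_role != "HE" and pixels.ndim == 2:
        pixels = pixels.astype(float)
    return TissueImage(pixels=pixels,
                       pixel_size=DEFAULT_PIXEL_SIZE_UM if pixel_size is None else pixel_size,
                       channel_role=channel_role)


def write_image(path: str | Path, image: TissueImage | np.ndarray) -> None:
    """Write an image as TIFF or PNG (by extension)."""
    path = Path(path)
    pixels = image.pixels if isinstance(image, TissueImage) else np.asarray(image)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, pixels)
    else:
        if pixels.dtype not in (np.uint8, np.uint16):
            pixels = pixels.astype(np.uint8)
        iio.imwrite(path, pixels)


def read_label_map(path: str | Path, pixel_size: float | None = None) -> InstanceSet:
    """Read a single-channel integer label image as an :class:`InstanceSet`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    if arr.ndim != 2:
        raise ValueError(f"label map must be single-channel, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        if np.any(arr != np.round(arr)):
            raise ValueError("label map must be integer-valued")
        arr = arr.astype(np.int64)
    if arr.size and arr.min() < 0:
        raise ValueError("negative labels are not allowed")
    ps = DEFAULT_PIXEL_SIZE_UM if pixel_size is None else pixel_size
    return InstanceSet(label_map=arr.astype(np.int32), pixel_size=ps)


def write_label_map(path: str | Path, instances: InstanceSet) -> None:
    path = Path(path)
    arr = instances.label_map
    dtype = np.uint16 if arr.max(initial=0) < 2**16 else np.int32
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr.astype(dtype))
    else:
        iio.imwrite(path, arr.astype(dtype))


def instances_from_label_map(label_map: np.ndarray, pixel_size: float) -> InstanceSet:
    """Wrap an in-memory integer label map as an :class:`InstanceSet`."""
    return InstanceSet(label_map=np.asarray(label_map, dtype=np.int32), pixel_size=pixel_size)
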