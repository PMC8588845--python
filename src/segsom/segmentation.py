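"""Nucleus instance segmentation from brightfield tissue images.

The image is processed in overlapping 256x256 tiles.  A pluggable backend
assigns every tile pixel a probability of being background, nucleus, or the
boundary between nuclei; overlapping tile predictions are blended with a
linear ramp, pixels take the argmax class, and 4-connected components of the
nucleus class become instances.  Any callable with the 3-class probability
contract can serve as backend (e.g. an externally trained CNN); the bundled
classical backend (optical-density thresholding + distance-transform
watershed, boundary = watershed ridge) keeps the pipeline runnable without
trained weights.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from .io import InstanceSet, TissueImage

__all__ = [
    "TileGrid", "split_into_tiles", "classical_backend", "classify_pixels",
    "merge_probabilities", "merge_tile_probabilities", "extract_instances",
    "boundary_weight_map", "segment_image",
]

# channel order of every probability map in this module
BACKGROUND, NUCLEUS, BOUNDARY = 0, 1, 2


@dataclasses.dataclass
class TileGrid:
    """Origins of overlapping tiles covering an image."""

    image_shape: tuple
    tile_size_px: int
    overlap_px: int
    origins: list  # of (row_offset, col_offset)


def _axis_offsets(extent: int, tile: int, overlap: int) -> list[int]:
    if extent <= tile:
        return [0]
    step = tile - overlap
    offsets = list(range(0, extent - tile, step))
    offsets.append(extent - tile)  # clamp the last tile to the edge
    return offsets


def split_into_tiles(image: TissueImage | np.ndarray, tile_size_px: int = 256,
                     overlap_px: int = 32) -> TileGrid:
    """Cover the image with overlapping ``tile_size_px`` square tiles.

    Consecutive origins differ by ``tile_size_px - overlap_px`` except the
    last per axis, which is clamped so the tile ends at the image edge.
    Images smaller than one tile yield a single origin at (0, 0); the tile
    is reflect-padded at prediction time.
    """
    if overlap_px >= tile_size_px:
        raise ValueError(f"overlap ({overlap_px}) must be < tile size ({tile_size_px})")
    if overlap_px < 0:
        raise ValueError("overlap must be >= 0")
    pixels = image.pixels if isinstance(image, TissueImage) else np.asarray(image)
    h, w = pixels.shape[:2]
    origins = [(r, c) for r in _axis_offsets(h, tile_size_px, overlap_px)
               for c in _axis_offsets(w, tile_size_px, overlap_px)]
    return TileGrid(image_shape=(h, w), tile_size_px=tile_size_px,
                    overlap_px=overlap_px, origins=origins)


def _to_grayscale(tile: np.ndarray) -> np.ndarray:
    tile = np.asarray(tile, dtype=float)
    if tile.ndim == 3:
        tile = tile @ np.array([0.2125, 0.7154, 0.0721])
    return tile


def classical_backend(tile: np.ndarray, min_distance_px: int = 10) -> np.ndarray:
    """Classical 3-class pixel classifier: threshold + watershed.

    Nuclei are assumed dark on a bright background (hematoxylin).  Pixels
    darker than the Otsu threshold are foreground; a distance-transform
    watershed splits touching nuclei and its ridge pixels form the boundary
    class.  Probabilities are hard 0/1 per pixel.
    """
    gray = _to_grayscale(tile)
    h, w = gray.shape
    probs = np.zeros((h, w, 3))
    if np.ptp(gray) < 1e-9:  # flat tile: all background
        probs[:, :, BACKGROUND] = 1.0
        return probs
    from skimage.filters import threshold_otsu

    fg = gray < threshold_otsu(gray)
    if not fg.any():
        probs[:, :, BACKGROUND] = 1.0
        return probs
    distance = ndi.distance_transform_edt(fg)
    peak_mask = np.zeros_like(fg)
    peaks = peak_local_max(distance, min_distance=min_distance_px, labels=fg,
                           exclude_border=False)
    peak_mask[tuple(peaks.T)] = True
    # merge co-equal plateau peaks so a single convex nucleus gets one marker
    markers, n_markers = ndi.label(ndi.binary_dilation(peak_mask, iterations=2))
    if n_markers == 0:
        markers, _ = ndi.label(fg)
    labels = watershed(-distance, markers, mask=fg, watershed_line=True)
    ridge = fg & (labels == 0)
    probs[:, :, NUCLEUS] = (labels > 0)
    probs[:, :, BOUNDARY] = ridge
    probs[:, :, BACKGROUND] = ~fg
    return probs


def _validate_probs(probs: np.ndarray, shape: tuple) -> np.ndarray:
    probs = np.asarray(probs, dtype=float)
    if probs.shape != (*shape, 3):
        raise ValueError(f"backend returned shape {probs.shape}, expected {(*shape, 3)}")
    if probs.min() < -1e-9 or probs.max() > 1 + 1e-9:
        raise ValueError("backend probabilities outside [0, 1]")
    sums = probs.sum(axis=2)
    if np.max(np.abs(sums - 1.0)) > 1e-6:
        raise ValueError("backend probabilities do not sum to 1 per pixel")
    return probs


def classify_pixels(tile: np.ndarray, backend=classical_backend) -> np.ndarray:
    """Run a 3-class backend on one tile and validate its contract."""
    tile = np.asarray(tile)
    return _validate_probs(backend(tile), tile.shape[:2])


def merge_probabilities(p1: np.ndarray, p2: np.ndarray, d: np.ndarray | float) -> np.ndarray:
    """Blend two probability maps over their overlap: ``(1 - d) * p2 + d * p1``.

    ``d`` is the per-pixel weight of the earlier tile ``p1``, in [0, 1].
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    d = np.asarray(d, dtype=float)
    if np.any(d < 0) or np.any(d > 1):
        raise ValueError("blend weight d must lie in [0, 1]")
    if p1.shape != p2.shape:
        raise ValueError("overlap maps must share a shape")
    if d.ndim and d.ndim < p1.ndim and d.shape == p1.shape[:d.ndim]:
        d = d.reshape(d.shape + (1,) * (p1.ndim - d.ndim))
    try:
        return (1.0 - d) * p2 + d * p1
    except ValueError as exc:
        raise ValueError("blend weight shape does not broadcast over overlap") from exc


def _ramp(length: int) -> np.ndarray:
    """Linear ramp 1 -> 0 across an overlap band of ``length`` pixels."""
    if length == 1:
        return np.array([0.5])
    return np.linspace(1.0, 0.0, length)


def merge_tile_probabilities(tile_probs: dict, grid: TileGrid) -> np.ndarray:
    """Assemble per-tile probability maps into one full-image map.

    Tiles are blended with :func:`merge_probabilities` using a linear ramp
    across each overlap band: the earlier tile's weight is 1 at its interior
    edge of the band and falls to 0 at the later tile's interior edge.
    Merging is separable — tiles merge left-to-right into row strips, then
    strips merge top-to-bottom.
    """
    h, w = grid.image_shape
    row_offsets = sorted({r for r, _ in grid.origins})
    col_offsets = sorted({c for _, c in grid.origins})

    def merge_1d(pieces, offsets, extent, axis):
        shape = list(pieces[0].shape)
        shape[axis] = extent
        out = np.zeros(shape)
        out_end = 0
        for off, piece in zip(offsets, pieces):
            end = off + piece.shape[axis]
            sl_new = [slice(None)] * piece.ndim
            sl_out = [slice(None)] * piece.ndim
            ov = out_end - off  # overlap with what is already written
            if ov > 0:
                d = _ramp(ov)  # weight of the earlier (already written) side
                d_shape = [1] * piece.ndim
                d_shape[axis] = ov
                sl_out[axis] = slice(off, off + ov)
                sl_new[axis] = slice(0, ov)
                out[tuple(sl_out)] = merge_probabilities(
                    out[tuple(sl_out)], piece[tuple(sl_new)], d.reshape(d_shape))
            sl_out[axis] = slice(max(off, out_end), end)
            sl_new[axis] = slice(max(0, ov), piece.shape[axis])
            out[tuple(sl_out)] = piece[tuple(sl_new)]
            out_end = max(out_end, end)
        return out

    strips = [merge_1d([tile_probs[(r, c)] for c in col_offsets], col_offsets, w, axis=1)
              for r in row_offsets]
    return merge_1d(strips, row_offsets, h, axis=0)


def extract_instances(prob_map: np.ndarray, pixel_size: float) -> InstanceSet:
    """Argmax-label the probability map and split nuclei into instances.

    Argmax ties resolve by class priority nucleus > boundary > background.
    Nucleus pixels are grouped by 4-connectivity, so a one-pixel
    boundary-class line (even diagonal) separates adjacent nuclei.
    """
    prob_map = np.asarray(prob_map, dtype=float)
    if prob_map.ndim != 3 or prob_map.shape[2] != 3:
        raise ValueError("expected an H x W x 3 probability map")
    # reorder channels so argmax's first-max rule realises the tie priority
    priority = prob_map[:, :, [NUCLEUS, BOUNDARY, BACKGROUND]]
    winner = np.argmax(priority, axis=2)  # 0 = nucleus
    nuclei = winner == 0
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])  # 4-connectivity
    labels, _ = ndi.label(nuclei, structure=structure)
    return InstanceSet(label_map=labels.astype(np.int32), pixel_size=pixel_size)


def boundary_weight_map(label_map: np.ndarray, w0: float = 10.0, sigma_w: float = 5.0,
                        class_balance: np.ndarray | None = None) -> np.ndarray:
    """Pixel loss-weight map emphasising gaps between adjacent nuclei.

    ``w(x) = w_c(x) + w0 * exp(-(d1 + d2)^2 / (2 sigma_w^2))`` where d1, d2
    are the distances (px) to the nearest and second-nearest nucleus.  With
    fewer than two nuclei d2 is infinite and w reduces to the class-balance
    term ``w_c`` (inverse class frequency, unit mean, by default).
    """
    if w0 < 0 or sigma_w <= 0:
        raise ValueError("w0 must be >= 0 and sigma_w > 0")
    label_map = np.asarray(label_map)
    h, w = label_map.shape
    fg = label_map > 0
    if class_balance is None:
        freq_fg = fg.mean()
        wc = np.empty((h, w))
        if 0 < freq_fg < 1:
            wc[fg] = 0.5 / freq_fg
            wc[~fg] = 0.5 / (1.0 - freq_fg)
        else:
            wc[:] = 1.0
    else:
        wc = np.broadcast_to(np.asarray(class_balance, dtype=float), (h, w)).copy()

    labels = np.unique(label_map)
    labels = labels[labels > 0]
    if len(labels) < 2:
        return wc
    d1 = np.full((h, w), np.inf)
    d2 = np.full((h, w), np.inf)
    for lab in labels:
        dist = ndi.distance_transform_edt(label_map != lab)
        closer = dist < d1
        d2 = np.where(closer, d1, np.minimum(d2, dist))
        d1 = np.where(closer, dist, d1)
    # the border-emphasis term applies to background pixels only, so the
    # weight peaks in the gaps separating adjacent nuclei
    return wc + np.where(fg, 0.0, w0 * np.exp(-((d1 + d2) ** 2) / (2.0 * sigma_w**2)))


def segment_image(image: TissueImage, backend=classical_backend,
                  tile_size_px: int = 256, overlap_px: int = 32) -> InstanceSet:
    """Full tile-predict-merge-extract segmentation of one image."""
    pixels = image.pixels
    h, w = pixels.shape[:2]
    pad_h = max(0, tile_size_px - h)
    pad_w = max(0, tile_size_px - w)
    if pad_h or pad_w:
        pad = [(0, pad_h), (0, pad_w)] + ([(0, 0)] if pixels.ndim == 3 else [])
        pixels = np.pad(pixels, pad, mode="reflect")
    grid = split_into_tiles(pixels, tile_size_px, overlap_px)
    tile_probs = {}
    for (r, c) in grid.origins:
        tile = pixels[r:r + tile_size_px, c:c + tile_size_px]
        tile_probs[(r, c)] = classify_pixels(tile, backend)
    merged = merge_tile_probabilities(tile_probs, grid)
    merged = merged[:h, :w]  # crop any padding back off
    return extract_instances(merged, image.pixel_size)
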