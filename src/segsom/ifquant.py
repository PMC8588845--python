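"""Validation of in-silico classes against immunofluorescence.

The H&E-derived segmentation is mapped onto IF images of the same tissue:
the DAPI channel is registered to the (inverted-luminance) H&E image by
cross-correlation, a ring-shaped perinuclear region approximates each
cell's cytoplasm (3x3 dilation of the nucleus mask — eight iterations for
the larger epithelial cells, five for lymphocytes — minus the nucleus),
and the mean stain intensity inside the ring, normalized by the image-wide
mean over cells, is summarised per morphological class.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.signal import fftconvolve
from scipy.stats import mannwhitneyu

from .config import get_logger
from .io import InstanceSet, TissueImage

__all__ = ["RingSpec", "register_translation", "he_intensity", "ring_region",
           "stain_intensity", "normalize_per_image", "class_intensity_summary",
           "measure_instances"]

logger = get_logger(__name__)

#: 8-connected (Chebyshev) structuring element — the standard "3x3 kernel"
STRUCTURE_3X3 = np.ones((3, 3), dtype=bool)


@dataclasses.dataclass
class RingSpec:
    """Per-class dilation iteration counts for the perinuclear ring."""

    iterations_by_class: dict = dataclasses.field(
        default_factory=lambda: {"Lymphocyte": 5})
    default_iterations: int = 8  # epithelial and everything else

    def iterations_for(self, class_name: str) -> int:
        n = self.iterations_by_class.get(class_name, self.default_iterations)
        if n < 0:
            raise ValueError("iterations must be >= 0")
        return n


def he_intensity(image: TissueImage | np.ndarray) -> np.ndarray:
    """Inverted grayscale luminance of an H&E image (nuclei bright, like DAPI)."""
    pixels = image.pixels if isinstance(image, TissueImage) else np.asarray(image)
    pixels = np.asarray(pixels, dtype=float)
    if pixels.ndim == 3:
        pixels = pixels @ np.array([0.2125, 0.7154, 0.0721])
    return pixels.max() - pixels


def register_translation(reference: np.ndarray | TissueImage,
                         moving: np.ndarray | TissueImage) -> tuple:
    """Integer (dy, dx) shift aligning ``moving`` onto ``reference``.

    The shift maximises the normalized cross-correlation of the
    mean-subtracted intensities (zero-padded, so shifts up to the full
    image size are representable).  Shifting ``moving`` by (dy, dx) —
    positive = down/right — brings it into register with ``reference``.
    """
    ref = np.asarray(reference.pixels if isinstance(reference, TissueImage) else reference,
                     dtype=float)
    mov = np.asarray(moving.pixels if isinstance(moving, TissueImage) else moving,
                     dtype=float)
    if ref.ndim != 2 or mov.ndim != 2:
        raise ValueError("registration expects single-channel intensity images")
    if ref.std() == 0 or mov.std() == 0:
        raise ValueError("cannot register a flat (zero-variance) image")
    ref_c = (ref - ref.mean()) / ref.std()
    mov_c = (mov - mov.mean()) / mov.std()
    corr = fftconvolve(ref_c, mov_c[::-1, ::-1], mode="full")
    peak = np.unravel_index(np.argmax(corr), corr.shape)
    dy = int(peak[0] - (mov.shape[0] - 1))
    dx = int(peak[1] - (mov.shape[1] - 1))
    return dy, dx


def apply_shift(image: np.ndarray, shift: tuple) -> np.ndarray:
    """Shift an image by integer (dy, dx), zero-filling exposed pixels."""
    return ndi.shift(np.asarray(image, dtype=float), shift, order=0, cval=0.0)


def ring_region(mask: np.ndarray, iterations: int) -> np.ndarray:
    """Perinuclear ring: the 3x3-dilated mask minus the mask itself."""
    mask = np.asarray(mask).astype(bool)
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if iterations == 0:
        return np.zeros_like(mask)
    dilated = ndi.binary_dilation(mask, structure=STRUCTURE_3X3, iterations=iterations)
    return dilated & ~mask


def stain_intensity(ring: np.ndarray, if_image: np.ndarray | TissueImage) -> float:
    """Mean IF intensity under the ring; NaN (flagged) for an empty ring."""
    pixels = if_image.pixels if isinstance(if_image, TissueImage) else np.asarray(if_image)
    ring = np.asarray(ring).astype(bool)
    if not ring.any():
        logger.warning("empty ring; stain intensity undefined")
        return float("nan")
    return float(np.asarray(pixels, dtype=float)[ring].mean())


def normalize_per_image(values: np.ndarray) -> np.ndarray:
    """Divide each cell's intensity by the image-wide mean over cells.

    NaN (flagged) cells are ignored for the mean and stay NaN.  The
    operation is idempotent: normalizing normalized values is the identity.
    """
    values = np.asarray(values, dtype=float)
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        raise ValueError("no measurable cells in image")
    return values / finite.mean()


def measure_instances(instances: InstanceSet, if_image: np.ndarray | TissueImage,
                      class_of_instance: dict, ring_spec: RingSpec | None = None,
                      shift: tuple = (0, 0)) -> pd.DataFrame:
    """Per-cell ring intensities for one registered (image, IF channel) pair.

    Returns a table (instance, class, raw, normalized); rings are built in
    H&E space and the IF image is shifted into register first.
    """
    ring_spec = ring_spec or RingSpec()
    pixels = if_image.pixels if isinstance(if_image, TissueImage) else np.asarray(if_image)
    if shift != (0, 0):
        pixels = apply_shift(pixels, shift)
    rows = []
    for lab in instances.labels:
        lab = int(lab)
        cls = class_of_instance[lab]
        ring = ring_region(instances.label_map == lab, ring_spec.iterations_for(cls))
        ring &= instances.label_map == 0  # do not sample neighbouring nuclei
        rows.append({"instance": lab, "class": cls,
                     "raw": stain_intensity(ring, pixels)})
    df = pd.DataFrame(rows)
    df["normalized"] = normalize_per_image(df["raw"].to_numpy())
    return df


def class_intensity_summary(normalized: np.ndarray, classes,
                            contrast_class: str | None = None):
    """Per-class intensity distribution summary and a class-vs-rest test.

    Returns ``(summary_table, p_value)``; the p-value is a two-sided
    Mann-Whitney rank-sum test of ``contrast_class`` against all other
    cells (None: no test, p = NaN).  Classes with no cells are excluded
    with a warning.
    """
    values = np.asarray(normalized, dtype=float)
    classes = np.asarray(classes)
    ok = np.isfinite(values)
    values, classes = values[ok], classes[ok]
    present = pd.unique(classes)
    if len(present) < 2:
        raise ValueError("need >= 2 classes with measurable cells")
    rows = []
    for cls in present:
        v = values[classes == cls]
        if v.size == 0:
            logger.warning("class %s has no measurable cells; excluded", cls)
            continue
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        rows.append({"class": cls, "n": int(v.size), "mean": float(v.mean()),
                     "median": float(med), "iqr": float(q3 - q1)})
    summary = pd.DataFrame(rows).set_index("class")
    p_value = float("nan")
    if contrast_class is not None:
        in_cls = values[classes == contrast_class]
        rest = values[classes != contrast_class]
        if in_cls.size and rest.size:
            if np.ptp(values) == 0:
                p_value = 1.0  # identical intensities: no enrichment
            else:
                _, p_value = mannwhitneyu(in_cls, rest, alternative="two-sided")
        p_value = float(p_value)
    return summary, p_value
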