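import numpy as np
import pytest

from segsom import synthetic
from segsom.io import InstanceSet


@pytest.fixture(scope="session")
def small_tissue():
    """One small six-class tissue image with ground truth (seeded)."""
    spec = synthetic.TissueSpec(
        image_size_px=900,
        class_counts={"Debris": 8, "Lymphocyte": 18, "Epithelial1": 8,
                      "Epithelial2": 5, "Epithelial3": 10, "Fibroblast": 6},
        seed=7,
    )
    return synthetic.gen_tissue(spec)


@pytest.fixture
def disc_mask():
    """A 10 um disc mask at 0.2 um/px (radius 25 px)."""
    return synthetic.gen_nucleus(
        synthetic.NucleusSpec(major_um=10, minor_um=10, jitter_amp=0.0), 0.2)


def place_discs(positions, diameter_um=8.0, canvas_px=300, pixel_size=0.2):
    """Label map with one disc per (row, col) position; labels 1..K."""
    label_map = np.zeros((canvas_px, canvas_px), dtype=np.int32)
    mask = synthetic.gen_nucleus(
        synthetic.NucleusSpec(major_um=diameter_um, minor_um=diameter_um,
                              jitter_amp=0.0), pixel_size)
    h, w = mask.shape
    for k, (r, c) in enumerate(positions, start=1):
        label_map[r:r + h, c:c + w][mask > 0] = k
    return InstanceSet(label_map=label_map, pixel_size=pixel_size)
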