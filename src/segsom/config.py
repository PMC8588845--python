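"""Global pipeline configuration and seeded randomness.

All stages of the pipeline read their tunable constants from a single
:class:`PipelineConfig`.  Every stochastic stage (PCA solver, SOM init and
shuffling, NMF, cross-validation) derives its own child seed from the one
global ``seed`` via :func:`child_seed`, so a full run is reproducible from a
single integer.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from contextlib import contextmanager
from pathlib import Path

import numpy as np

__all__ = ["PipelineConfig", "child_seed", "child_rng", "get_logger", "stage_timer"]

#: default physical resolution of the 40x brightfield scans, micrometres per pixel
DEFAULT_PIXEL_SIZE_UM = 0.20


@dataclasses.dataclass
class PipelineConfig:
    """Constants of the full morphology/SOM/interaction pipeline.

    Defaults are the published operating point: 170 px aligned crops,
    1000-dimensional PCA embedding, a 7x7 hexagonal SOM trained for 100
    epochs, six morphological classes, a 50 um Gaussian proximity kernel,
    100 NMF interaction features of which 5 are selected, and 5-fold
    cross-validation repeated 5000 times.
    """

    crop_size_px: int = 170
    pca_dim: int = 1000
    grid_rows: int = 7
    grid_cols: int = 7
    epochs: int = 100
    som_restarts: int = 3  # restarts ranked by topographic error
    n_clusters: int = 6
    kernel_sigma_um: float = 50.0
    kernel: str = "gaussian"  # or "exponential" (unsquared distance)
    nmf_components: int = 100
    l1_weight: float = 0.1
    n_selected: int = 5
    cv_folds: int = 5
    cv_iterations: int = 5000
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    tile_size_px: int = 256
    tile_overlap_px: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "crop_size_px", "pca_dim", "grid_rows", "grid_cols", "epochs",
            "som_restarts",
            "n_clusters", "nmf_components", "n_selected", "cv_folds",
            "cv_iterations", "tile_size_px",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.kernel_sigma_um <= 0:
            raise ValueError("kernel_sigma_um must be > 0")
        if self.l1_weight < 0:
            raise ValueError("l1_weight must be >= 0")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.kernel not in ("gaussian", "exponential"):
            raise ValueError(f"unknown kernel {self.kernel!r}")

    @property
    def n_nodes(self) -> int:
        return self.grid_rows * self.grid_cols

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load a config from a JSON or YAML key/value file."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")


def child_seed(seed: int, stage: str) -> int:
    """Derive a deterministic per-stage seed (< 2**31) from the global seed."""
    import hashlib

    digest = hashlib.sha256(stage.encode()).digest()
    words = [int.from_bytes(digest[i:i + 4], "little") for i in range(0, 16, 4)]
    ss = np.random.SeedSequence([seed, *words])
    return int(ss.generate_state(1, np.uint64)[0] % (2**31))


def child_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(child_seed(seed, stage))


_LOGGER_NAME = "segsom"


def get_logger(name: str = _LOGGER_NAME) -> logging.Logger:
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s: %(message)s"))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    return logger


@contextmanager
def stage_timer(stage: str, logger: logging.Logger | None = None):
    """Log wall-clock duration of a pipeline stage to stderr."""
    logger = logger or get_logger()
    t0 = time.perf_counter()
    yield
    logger.info("%s finished in %.2f s", stage, time.perf_counter() - t0)
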