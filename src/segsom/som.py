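"""Online self-organizing map on a hexagonal grid.

A 7x7 hexagonal grid of prototype vectors (nodes) is trained online: every
sample in turn is matched to its best-matching unit (BMU, the node with the
smallest Euclidean distance), and all nodes move toward the sample by

    w <- w + G(g; r(t)) * a(t) * (v - w)

where ``g`` is the hexagonal grid distance between the node and the BMU,
``G(g) = exp(-g^2 / (2 r(t)^2))`` is a Gaussian neighborhood with G(0) = 1,
and ``a(t)`` in [0, 1] and ``r(t) > 0`` decay monotonically over epochs.
Adjacent nodes therefore learn similar prototypes: the trained grid is a
topographic map of nuclear shape, with size and aspect ratio emerging along
the two grid axes.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

__all__ = ["HexGrid", "TrainSchedule", "SOMGrid", "grid_distance", "find_bmu",
           "update_step", "train", "train_selected", "assign_all",
           "quantization_error", "topographic_error", "save_som", "load_som"]


class HexGrid:
    """Hexagonal node lattice, odd-row offset layout, row-major indexing.

    Node ``i`` sits at ``(row, col) = divmod(i, cols)``; odd rows are
    shifted half a cell right, so every interior node has six nearest
    neighbors.  Distances are exact hexagonal lattice distances (minimum
    number of neighbor steps), computed in axial coordinates.
    """

    def __init__(self, rows: int, cols: int):
        if rows < 1 or cols < 1:
            raise ValueError("grid must be at least 1x1")
        self.rows = rows
        self.cols = cols
        rc = np.array([(r, c) for r in range(rows) for c in range(cols)])
        self.row = rc[:, 0]
        self.col = rc[:, 1]
        # odd-r offset -> axial coordinates
        self.axial_q = self.col - (self.row - (self.row & 1)) // 2
        self.axial_r = self.row

    @property
    def n_nodes(self) -> int:
        return self.rows * self.cols

    def index_of(self, row: int, col: int) -> int:
        if not (0 <= row < self.rows and 0 <= col < self.cols):
            raise IndexError(f"node ({row}, {col}) off the {self.rows}x{self.cols} grid")
        return row * self.cols + col

    def distance_matrix(self) -> np.ndarray:
        dq = self.axial_q[:, None] - self.axial_q[None, :]
        dr = self.axial_r[:, None] - self.axial_r[None, :]
        return ((np.abs(dq) + np.abs(dr) + np.abs(dq + dr)) // 2).astype(int)


def grid_distance(grid: HexGrid, node_a: int, node_b: int) -> int:
    """Hex lattice distance (number of neighbor steps) between two nodes."""
    n = grid.n_nodes
    if not (0 <= node_a < n and 0 <= node_b < n):
        raise IndexError(f"node index out of range for {n}-node grid")
    dq = int(grid.axial_q[node_a] - grid.axial_q[node_b])
    dr = int(grid.axial_r[node_a] - grid.axial_r[node_b])
    return (abs(dq) + abs(dr) + abs(dq + dr)) // 2


@dataclasses.dataclass
class TrainSchedule:
    """Per-epoch learning rate a(t) and neighborhood radius r(t).

    Defaults decay linearly: a from 0.5 to 0.01 and r from half the larger
    grid dimension to 0.5, over ``epochs`` epochs.  Both sequences must be
    monotonically nonincreasing.
    """

    epochs: int = 100
    learning_rate: np.ndarray | None = None
    radius: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate is None:
            self.learning_rate = np.linspace(0.5, 0.01, self.epochs)
        if self.radius is None:
            self.radius = np.linspace(1.0, 0.5, self.epochs)  # replaced by for_grid
        self.learning_rate = np.asarray(self.learning_rate, dtype=float)
        self.radius = np.asarray(self.radius, dtype=float)
        for name, seq in (("learning_rate", self.learning_rate), ("radius", self.radius)):
            if len(seq) != self.epochs:
                raise ValueError(f"{name} must have one value per epoch")
            if np.any(np.diff(seq) > 1e-12):
                raise ValueError(f"{name} must be monotonically nonincreasing")
        if self.learning_rate.min() < 0 or self.learning_rate.max() > 1:
            raise ValueError("learning rate must lie in [0, 1]")
        if self.radius.min() <= 0:
            raise ValueError("radius must stay > 0")

    @classmethod
    def for_grid(cls, rows: int, cols: int, epochs: int = 100,
                 a_start: float = 0.5, a_end: float = 0.01,
                 r_end: float = 0.5) -> "TrainSchedule":
        r_start = max(max(rows, cols) / 2.0, r_end)
        return cls(epochs=epochs,
                   learning_rate=np.linspace(a_start, a_end, epochs),
                   radius=np.linspace(r_start, r_end, epochs))


@dataclasses.dataclass
class SOMGrid:
    """A hexagonal grid of prototype vectors with training history."""

    hex: HexGrid
    W: np.ndarray  # (n_nodes, D)
    trained: bool = False
    history: list = dataclasses.field(default_factory=list)  # (epoch, mean QE)

    @classmethod
    def initialize(cls, rows: int, cols: int, dim: int, seed: int = 0) -> "SOMGrid":
        """Random standard-normal node vectors, seeded."""
        rng = np.random.default_rng(seed)
        hexgrid = HexGrid(rows, cols)
        return cls(hex=hexgrid, W=rng.standard_normal((hexgrid.n_nodes, dim)))

    @property
    def dim(self) -> int:
        return self.W.shape[1]


def find_bmu(grid: SOMGrid, v: np.ndarray) -> int:
    """Index of the best-matching unit; ties break to the lowest index."""
    v = np.asarray(v, dtype=float)
    if v.shape != (grid.dim,):
        raise ValueError(f"embedding has dim {v.shape}, grid expects ({grid.dim},)")
    diff = grid.W - v
    return int(np.argmin(np.einsum("ij,ij->i", diff, diff)))


def update_step(grid: SOMGrid, v: np.ndarray, bmu: int, epoch: int,
                schedule: TrainSchedule, dist_matrix: np.ndarray | None = None) -> None:
    """Move every node toward ``v`` by the neighborhood-weighted step (in place)."""
    if dist_matrix is None:
        dist_matrix = grid.hex.distance_matrix()
    a = schedule.learning_rate[epoch]
    r = schedule.radius[epoch]
    g = dist_matrix[bmu]
    G = np.exp(-(g.astype(float) ** 2) / (2.0 * r * r))
    grid.W += (G * a)[:, None] * (np.asarray(v, dtype=float) - grid.W)


def train(grid: SOMGrid, X: np.ndarray, schedule: TrainSchedule | None = None,
          seed: int = 0) -> SOMGrid:
    """Online-train the map: per epoch, present all samples without replacement.

    The sample order is reshuffled each epoch from ``seed``; the history
    records the mean quantization error of each epoch (BMU distances
    measured as samples are presented).  Training is fully deterministic
    given ``seed``, the data and the initial grid.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < 1 or X.shape[1] != grid.dim:
        raise ValueError(f"need (N >= 1) x {grid.dim} data, got {X.shape}")
    if schedule is None:
        schedule = TrainSchedule.for_grid(grid.hex.rows, grid.hex.cols)
    rng = np.random.default_rng(seed)
    dist_matrix = grid.hex.distance_matrix()
    n = X.shape[0]
    for epoch in range(schedule.epochs):
        order = rng.permutation(n)
        qe_sum = 0.0
        for i in order:
            v = X[i]
            diff = grid.W - v
            d2 = np.einsum("ij,ij->i", diff, diff)
            bmu = int(np.argmin(d2))
            qe_sum += np.sqrt(d2[bmu])
            a = schedule.learning_rate[epoch]
            r = schedule.radius[epoch]
            g = dist_matrix[bmu]
            G = np.exp(-(g.astype(float) ** 2) / (2.0 * r * r))
            grid.W += (G * a)[:, None] * (v - grid.W)
        grid.history.append((epoch, qe_sum / n))
    grid.trained = True
    return grid


def assign_all(grid: SOMGrid, X: np.ndarray, chunk: int = 1024) -> np.ndarray:
    """BMU index per row of ``X`` (RMSE argmin == Euclidean argmin)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != grid.dim:
        raise ValueError(f"data dim {X.shape[1]} != grid dim {grid.dim}")
    out = np.empty(X.shape[0], dtype=int)
    w_sq = np.einsum("ij,ij->i", grid.W, grid.W)
    for start in range(0, X.shape[0], chunk):
        xb = X[start:start + chunk]
        d2 = w_sq[None, :] - 2.0 * xb @ grid.W.T  # + |x|^2, constant per row
        out[start:start + chunk] = np.argmin(d2, axis=1)
    return out


def quantization_error(grid: SOMGrid, X: np.ndarray) -> float:
    """Mean Euclidean distance from each sample to its BMU prototype."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    bmus = assign_all(grid, X)
    return float(np.mean(np.linalg.norm(X - grid.W[bmus], axis=1)))


def topographic_error(grid: SOMGrid, X: np.ndarray, chunk: int = 1024) -> float:
    """Fraction of samples whose best and second-best nodes are not adjacent.

    The standard topology-preservation measure: low values mean neighboring
    prototypes tile the data manifold smoothly; twisted or diagonally folded
    maps score visibly higher.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    D = grid.hex.distance_matrix()
    w_sq = np.einsum("ij,ij->i", grid.W, grid.W)
    bad = 0
    for start in range(0, X.shape[0], chunk):
        xb = X[start:start + chunk]
        d2 = w_sq[None, :] - 2.0 * xb @ grid.W.T
        top2 = np.argpartition(d2, 1, axis=1)[:, :2]
        # argpartition does not order the pair; sort by distance
        first = np.where(d2[np.arange(len(xb)), top2[:, 0]]
                         <= d2[np.arange(len(xb)), top2[:, 1]],
                         top2[:, 0], top2[:, 1])
        second = np.where(first == top2[:, 0], top2[:, 1], top2[:, 0])
        bad += int((D[first, second] > 1).sum())
    return bad / X.shape[0]


def train_selected(rows: int, cols: int, X: np.ndarray,
                   schedule: TrainSchedule | None = None, seed: int = 0,
                   n_restarts: int = 3) -> SOMGrid:
    """Train ``n_restarts`` maps from derived seeds; keep the best-organized.

    Online SOMs occasionally lock into a twisted (diagonally folded)
    configuration during the coarse phase.  Restarts are ranked by
    topographic error, ties broken by final quantization error then by
    restart index — an unsupervised model-selection step.  With one restart
    this reduces to :func:`train`.
    """
    from .config import child_seed

    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    best = None
    best_key = None
    for restart in range(n_restarts):
        grid = SOMGrid.initialize(rows, cols, dim=X.shape[1],
                                  seed=child_seed(seed, f"som-init-{restart}"))
        train(grid, X, schedule, seed=child_seed(seed, f"som-shuffle-{restart}"))
        key = (topographic_error(grid, X), grid.history[-1][1], restart)
        if best_key is None or key < best_key:
            best, best_key = grid, key
    return best


def save_som(path: str | Path, grid: SOMGrid, schedule: TrainSchedule | None = None,
             seed: int | None = None) -> None:
    """Serialize a grid (and optionally its schedule/seed) to an .npz archive."""
    meta = {"rows": grid.hex.rows, "cols": grid.hex.cols, "dim": grid.dim,
            "trained": grid.trained, "seed": seed}
    arrays = {"W": grid.W, "history": np.array(grid.history, dtype=float),
              "meta": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)}
    if schedule is not None:
        arrays["learning_rate"] = schedule.learning_rate
        arrays["radius"] = schedule.radius
    np.savez(path, **arrays)


def load_som(path: str | Path) -> SOMGrid:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        grid = SOMGrid(hex=HexGrid(meta["rows"], meta["cols"]), W=data["W"].copy(),
                       trained=bool(meta["trained"]),
                       history=[tuple(h) for h in data["history"]])
    return grid
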