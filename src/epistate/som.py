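"""Self-organizing map over per-region epigenetic/expression signatures.

Feature vectors (histone-mark enrichments, DNA methylation, expression) are
centre-scaled to mean 0 / sd 1 per column, then mapped onto a hexagonal
grid by online SOM training: per step the best-matching unit (BMU) is found
by Euclidean distance and the codebook of every node within the current
neighbourhood radius is pulled toward the sample, with a Gaussian weight
that shrinks during training.  Nodes end up summarizing sets of regions
with very similar signatures, and neighbouring nodes hold similar sets.

Grid size, epoch count and the learning-rate/radius schedules are exposed
because no single choice is canonical; defaults are a 10x10 grid, 100
epochs, learning rate 0.05 -> 0.01 and radius 2/3 of the grid diagonal
-> 0, both decaying linearly over all steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FeatureMatrix",
    "SOMModel",
    "center_scale",
    "hex_positions",
    "train_som",
    "bmu",
    "assign_all",
    "node_summaries",
    "quantization_error",
]


@dataclass
class FeatureMatrix:
    """Centre-scaled region-by-feature matrix."""

    values: np.ndarray  # (n_regions, n_features), scaled
    region_ids: list[str]
    feature_names: list[str]
    means: np.ndarray = field(default_factory=lambda: np.array([]))
    sds: np.ndarray = field(default_factory=lambda: np.array([]))


def center_scale(
    raw: np.ndarray,
    region_ids: list[str] | None = None,
    feature_names: list[str] | None = None,
) -> FeatureMatrix:
    """Scale each column to mean 0, sd 1; constant columns become all zeros."""
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2:
        raise ValueError("expected a 2-D feature array")
    if not np.all(np.isfinite(raw)):
        raise ValueError("non-finite feature values")
    means = raw.mean(axis=0)
    sds = raw.std(axis=0, ddof=0)
    safe = np.where(sds > 0, sds, 1.0)
    scaled = (raw - means) / safe
    scaled[:, sds == 0] = 0.0
    n, d = raw.shape
    return FeatureMatrix(
        scaled,
        region_ids or [f"r{i}" for i in range(n)],
        feature_names or [f"f{j}" for j in range(d)],
        means,
        sds,
    )


def hex_positions(width: int, height: int) -> np.ndarray:
    """Node coordinates on a hex lattice: odd rows offset by 0.5, row
    spacing sqrt(3)/2.  Node index = row * width + col."""
    pos = np.empty((width * height, 2))
    for row in range(height):
        for col in range(width):
            pos[row * width + col] = (col + 0.5 * (row % 2),
                                      row * np.sqrt(3.0) / 2.0)
    return pos


@dataclass
class SOMModel:
    width: int
    height: int
    codebook: np.ndarray  # (n_nodes, n_features)
    positions: np.ndarray  # (n_nodes, 2) hex coordinates
    feature_names: list[str]
    seed: int
    epochs: int
    lr: tuple[float, float]
    radius: tuple[float, float]
    assignments: np.ndarray | None = None  # region index -> node index

    @property
    def n_nodes(self) -> int:
        return self.width * self.height


def train_som(
    features: FeatureMatrix,
    width: int = 10,
    height: int = 10,
    epochs: int = 100,
    lr: tuple[float, float] = (0.05, 0.01),
    radius: tuple[float, float] | None = None,
    seed: int = 0,
) -> SOMModel:
    """Online SOM training, deterministic given ``seed``.

    The codebook is initialized by seeded sampling of input rows.  Samples
    are visited in a freshly shuffled order each epoch (per-epoch derived
    seed).  Per step the BMU's neighbourhood (grid distance <= current
    radius sigma) moves by alpha * exp(-d^2/(2 sigma^2)) * (x - c); with
    sigma = 0 only the BMU moves, which is online k-means.
    """
    x = np.asarray(features.values, dtype=float)
    if x.ndim != 2 or x.shape[0] == 0:
        raise ValueError("empty feature matrix")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite features")
    n, d = x.shape
    n_nodes = width * height
    pos = hex_positions(width, height)
    if radius is None:
        diag = float(np.linalg.norm(pos[0] - pos[-1])) if n_nodes > 1 else 0.0
        radius = (2.0 / 3.0 * diag, 0.0)

    rng = np.random.default_rng(seed)
    codebook = x[rng.integers(0, n, n_nodes)].copy()

    # pairwise grid distances between nodes, fixed for the run
    grid_d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=2)

    total = epochs * n
    t = 0
    for epoch in range(epochs):
        erng = np.random.default_rng(np.random.SeedSequence([seed, epoch]))
        order = erng.permutation(n)
        for i in order:
            frac = t / max(total - 1, 1)
            alpha = lr[0] + (lr[1] - lr[0]) * frac
            sigma = radius[0] + (radius[1] - radius[0]) * frac
            xi = x[i]
            dist2 = ((codebook - xi) ** 2).sum(axis=1)
            best = int(np.argmin(dist2))  # argmin ties -> lowest index
            if sigma > 0:
                nbr = np.where(grid_d[best] <= sigma)[0]
                h = np.exp(-(grid_d[best, nbr] ** 2) / (2.0 * sigma * sigma))
                codebook[nbr] += alpha * h[:, None] * (xi - codebook[nbr])
            else:
                codebook[best] += alpha * (xi - codebook[best])
            t += 1

    model = SOMModel(width, height, codebook, pos, features.feature_names,
                     seed, epochs, lr, radius)
    model.assignments = assign_all(model, x)
    return model


def bmu(model: SOMModel, x: np.ndarray) -> int:
    """Best-matching unit: argmin Euclidean distance, ties to lowest index."""
    dist2 = ((model.codebook - np.asarray(x, dtype=float)) ** 2).sum(axis=1)
    return int(np.argmin(dist2))


def assign_all(model: SOMModel, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    d2 = ((x[:, None, :] - model.codebook[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1)


def quantization_error(model: SOMModel, x: np.ndarray) -> float:
    """Mean squared distance of samples to their BMU codebooks."""
    x = np.asarray(x, dtype=float)
    d2 = ((x[:, None, :] - model.codebook[None, :, :]) ** 2).sum(axis=2)
    return float(d2.min(axis=1).mean())


def node_summaries(
    model: SOMModel,
    features: FeatureMatrix,
    rank_by: str,
) -> pd.DataFrame:
    """Per-node mean of each feature plus member count, ranked by the node
    average of ``rank_by`` (descending).  Empty nodes report count 0 and
    NaN means."""
    if rank_by not in features.feature_names:
        raise ValueError(f"unknown feature {rank_by!r}")
    assign = (model.assignments if model.assignments is not None
              else assign_all(model, features.values))
    rows = []
    for node in range(model.n_nodes):
        members = np.where(assign == node)[0]
        row: dict[str, float] = {"node": node, "count": len(members)}
        for j, name in enumerate(features.feature_names):
            row[f"mean_{name}"] = (
                float(features.values[members, j].mean()) if len(members)
                else np.nan
            )
        rows.append(row)
    df = pd.DataFrame(rows)
    df = df.sort_values(f"mean_{rank_by}", ascending=False,
                        na_position="last", kind="mergesort")
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)
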