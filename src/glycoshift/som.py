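"""Toroidal Kohonen self-organizing maps and the diversity-based data split.

The map is a rectangular grid of neurons, each carrying a 23-element
weight vector, trained by the classic winner-takes-most rule: the best
matching unit (minimum Euclidean distance) and its toroidal Gaussian
neighbourhood move toward each presented object while the learning rate
and neighbourhood radius decay linearly over the epochs.  Besides
visualising the chemical diversity of a dataset, the map drives the
approximately 3:1 train/test split: test compounds are drawn from singly
occupied neurons so that they are spread over distinct map regions and
structurally distinct from every training compound.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .encoding import N_DESCRIPTORS, descriptor_matrix
from .records import SpectrumRecord

__all__ = ["SOMGrid", "train_som", "winner", "diversity_split", "toroidal_distance2", "grid_side_for_split"]


@dataclass
class SOMGrid:
    """A trained map: ``weights`` has shape (height, width, n_features)."""

    width: int
    height: int
    weights: np.ndarray
    toroidal: bool = True
    training_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("grid must have at least one neuron")
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape[:2] != (self.height, self.width):
            raise ValueError("weight array shape does not match the grid")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("non-finite weights")

    @property
    def n_neurons(self) -> int:
        return self.width * self.height


def toroidal_distance2(a: tuple[int, int], b: tuple[int, int], height: int, width: int, toroidal: bool = True) -> float:
    """Squared grid distance between neuron coordinates (row, col)."""
    dr = abs(a[0] - b[0])
    dc = abs(a[1] - b[1])
    if toroidal:
        dr = min(dr, height - dr)
        dc = min(dc, width - dc)
    return float(dr * dr + dc * dc)


def _grid_distance2_maps(height: int, width: int, toroidal: bool) -> np.ndarray:
    """d2[r0, c0, r1, c1] = squared grid distance; built once per training."""
    rows = np.arange(height)
    cols = np.arange(width)
    dr = np.abs(rows[:, None] - rows[None, :])
    dc = np.abs(cols[:, None] - cols[None, :])
    if toroidal:
        dr = np.minimum(dr, height - dr)
        dc = np.minimum(dc, width - dc)
    return (dr[:, None, :, None] ** 2 + dc[None, :, None, :] ** 2).astype(float)


def _schedule(epoch: int, epochs: int, lr0: float, lr1: float, radius0: float) -> tuple[float, float]:
    frac = epoch / (epochs - 1) if epochs > 1 else 1.0
    return lr0 + (lr1 - lr0) * frac, radius0 * (1.0 - frac)


def train_som(
    X: np.ndarray,
    width: int,
    height: int,
    *,
    toroidal: bool = True,
    epochs: int = 100,
    learning_rate: tuple[float, float] = (0.5, 0.01),
    radius0: float | None = None,
    seed: int = 0,
) -> SOMGrid:
    """Train a Kohonen map on the descriptor matrix ``X`` (n x 23).

    Weights start as the data mean plus small seeded uniform noise; each
    epoch presents all objects in a fresh seeded order.  Deterministic
    for a given seed.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("X must be a non-empty 2-D matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite descriptors")
    rng = np.random.default_rng(seed)
    if radius0 is None:
        radius0 = max(width, height) / 2.0
    lr0, lr1 = learning_rate
    mean = X.mean(axis=0)
    weights = mean[None, None, :] + rng.uniform(-0.5, 0.5, size=(height, width, X.shape[1]))
    d2 = _grid_distance2_maps(height, width, toroidal)
    for epoch in range(epochs):
        lr, radius = _schedule(epoch, epochs, lr0, lr1, radius0)
        for i in rng.permutation(X.shape[0]):
            x = X[i]
            diff = weights - x
            br, bc = np.unravel_index(np.argmin(np.einsum("hwk,hwk->hw", diff, diff)), (height, width))
            if radius > 1e-9:
                kernel = np.exp(-d2[br, bc] / (2.0 * radius * radius))
            else:
                kernel = np.zeros((height, width))
                kernel[br, bc] = 1.0
            weights -= (lr * kernel)[:, :, None] * diff
    grid = SOMGrid(
        width=width,
        height=height,
        weights=weights,
        toroidal=toroidal,
        training_params={"epochs": epochs, "learning_rate": list(learning_rate), "radius0": radius0, "seed": seed},
    )
    return grid


def winner(grid: SOMGrid, x: np.ndarray) -> tuple[int, int]:
    """Best matching unit for ``x``; ties resolve to the smallest (row, col)."""
    x = np.asarray(x, dtype=float)
    diff = grid.weights - x
    d2 = np.einsum("hwk,hwk->hw", diff, diff)
    return tuple(int(v) for v in np.unravel_index(np.argmin(d2), d2.shape))


def grid_side_for_split(n: int, factor: float = 1.3) -> int:
    """Square side with at least ``factor * n`` neurons (map sizing heuristic)."""
    target = factor * n
    side = max(1, math.isqrt(max(0, math.ceil(target) - 1)))
    while side * side < target - 1e-9:
        side += 1
    return side


def diversity_split(
    records: Sequence[SpectrumRecord],
    n_test: int,
    *,
    seed: int = 0,
    grid_side: int | None = None,
    epochs: int = 100,
) -> tuple[list[str], list[str]]:
    """Split records ~3:1 style into (train ids, test ids) via a Kohonen map.

    The map is trained on all records; test candidates are the records
    sitting alone on their winning neuron, from which ``n_test`` are
    picked greedily to maximise the minimum toroidal distance between
    chosen neurons (first pick seeded).  If singly occupied neurons are
    scarce, the least occupied multi-record neurons contribute one
    seeded record each, with a warning.
    """
    if n_test >= len(records):
        raise ValueError("n_test must be smaller than the number of records")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate record ids")
    if n_test == 0:
        return list(ids), []
    X, _ = descriptor_matrix(records)
    side = grid_side if grid_side is not None else grid_side_for_split(len(records))
    grid = train_som(X, side, side, epochs=epochs, seed=seed)
    occupants: dict[tuple[int, int], list[int]] = {}
    for i in range(len(records)):
        occupants.setdefault(winner(grid, X[i]), []).append(i)
    rng = np.random.default_rng(seed)
    singles = sorted(
        ((neuron, idxs[0]) for neuron, idxs in occupants.items() if len(idxs) == 1),
        key=lambda item: ids[item[1]],
    )
    pool = list(singles)
    if len(pool) < n_test:
        warnings.warn(
            f"only {len(pool)} singly occupied neurons for {n_test} test compounds; "
            "falling back to least-occupied neurons",
            stacklevel=2,
        )
        multi = sorted(
            ((neuron, idxs) for neuron, idxs in occupants.items() if len(idxs) > 1),
            key=lambda item: (len(item[1]), item[0]),
        )
        for neuron, idxs in multi:
            pick = int(rng.choice(idxs))
            pool.append((neuron, pick))
            if len(pool) >= n_test:
                break
    if len(pool) < n_test:
        raise ValueError("not enough neurons to assemble the requested test set")
    chosen: list[tuple[tuple[int, int], int]] = []
    first = int(rng.integers(len(pool)))
    chosen.append(pool.pop(first))
    while len(chosen) < n_test:
        best_j, best_key = 0, None
        for j, (neuron, idx) in enumerate(pool):
            min_d = min(
                toroidal_distance2(neuron, c_neuron, side, side, grid.toroidal) for c_neuron, _ in chosen
            )
            key = (min_d, ids[idx])
            # maximise the minimal distance; ties by smallest record id
            if best_key is None or min_d > best_key[0] or (min_d == best_key[0] and key[1] < best_key[1]):
                best_j, best_key = j, key
        chosen.append(pool.pop(best_j))
    test_idx = sorted(idx for _, idx in chosen)
    test_set = set(test_idx)
    train_ids = [ids[i] for i in range(len(records)) if i not in test_set]
    test_ids = [ids[i] for i in test_idx]
    return train_ids, test_ids
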