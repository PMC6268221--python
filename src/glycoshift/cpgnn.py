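"""Counterpropagation neural network for the nine structure tasks.

The network couples a toroidal Kohonen input layer (one 23-element
weight vector per neuron, trained on the sorted shift descriptors) to an
output layer aligned neuron-for-neuron with the map.  Each neuron's
output block holds, per task, one non-negative entry per class; during
training the winning neuron and its neighbourhood pull their input
weights toward the presented object and their output weights toward the
one-hot encoding of its labels, with a shared decaying rate/radius
schedule.  At prediction time the output layer acts as a look-up table:
the winning neuron's largest entry per task is the predicted class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .records import TASKS
from .som import SOMGrid, _grid_distance2_maps, _schedule, winner

__all__ = ["CPGNNModel", "grid_size_for", "train_cpgnn", "predict_cpgnn", "predict_many", "crossvalidate_10fold"]


def grid_size_for(n_train: int, factor: float = 1.3) -> tuple[int, int]:
    """Smallest square grid with at least ``factor * n_train`` neurons.

    With the conventional factor 1.3, 92 training cases give an 11 x 11
    map (121 neurons; a 10 x 10 map would offer only 100).
    """
    if n_train < 1:
        raise ValueError("n_train must be at least 1")
    target = factor * n_train
    side = max(1, math.isqrt(max(0, math.ceil(target) - 1)))
    while side * side < target - 1e-9:
        side += 1
    return side, side


@dataclass
class CPGNNModel:
    """Kohonen input layer plus per-task output look-up blocks."""

    kohonen: SOMGrid
    output_layer: dict[str, np.ndarray]  # task -> (height, width, n_classes)
    tasks: dict[str, tuple[str, ...]] = field(default_factory=lambda: dict(TASKS))
    epochs: int = 100

    def __post_init__(self) -> None:
        shape = (self.kohonen.height, self.kohonen.width)
        for task, block in self.output_layer.items():
            block = np.asarray(block, dtype=float)
            if block.shape != shape + (len(self.tasks[task]),):
                raise ValueError(f"output block for {task} misaligned with the Kohonen layer")
            if np.any(block < 0):
                raise ValueError(f"negative output weights for task {task}")
            self.output_layer[task] = block


def train_cpgnn(
    X: np.ndarray,
    Y: pd.DataFrame,
    grid_spec: tuple[int, int] | None = None,
    *,
    epochs: int = 100,
    learning_rate: tuple[float, float] = (0.5, 0.01),
    seed: int = 0,
    tasks: Mapping[str, Sequence[str]] | None = None,
) -> CPGNNModel:
    """Train the network on descriptors ``X`` and the label table ``Y``.

    ``Y`` has one column per task with single-letter class codes.  The
    grid defaults to :func:`grid_size_for` of the training size.  Output
    weights start as small uniform values in [0, 0.1); the update rule
    keeps them inside [0, 1], and neurons never visited keep their
    initial values so that predictions from them fall back to the
    largest (near-uniform) entry, i.e. effectively the tie rule.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("X must be a non-empty 2-D matrix")
    if len(Y) != X.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    task_alphabets = {t: tuple(a) for t, a in (tasks or {k: TASKS[k] for k in Y.columns}).items()}
    encoded: dict[str, np.ndarray] = {}
    for task, alphabet in task_alphabets.items():
        index = {c: i for i, c in enumerate(alphabet)}
        try:
            encoded[task] = np.array([index[v] for v in Y[task]], dtype=int)
        except KeyError as exc:
            raise ValueError(f"label {exc.args[0]!r} outside alphabet {alphabet} of task {task}") from exc
    if grid_spec is None:
        grid_spec = grid_size_for(X.shape[0])
    height, width = grid_spec
    rng = np.random.default_rng(seed)
    lr0, lr1 = learning_rate
    radius0 = max(width, height) / 2.0
    mean = X.mean(axis=0)
    weights = mean[None, None, :] + rng.uniform(-0.5, 0.5, size=(height, width, X.shape[1]))
    outputs = {
        task: rng.uniform(0.0, 0.1, size=(height, width, len(alphabet)))
        for task, alphabet in task_alphabets.items()
    }
    d2 = _grid_distance2_maps(height, width, toroidal=True)
    for epoch in range(epochs):
        lr, radius = _schedule(epoch, epochs, lr0, lr1, radius0)
        for i in rng.permutation(X.shape[0]):
            x = X[i]
            diff = weights - x
            br, bc = np.unravel_index(np.argmin(np.einsum("hwk,hwk->hw", diff, diff)), (height, width))
            if radius > 1e-9:
                kernel = lr * np.exp(-d2[br, bc] / (2.0 * radius * radius))
            else:
                kernel = np.zeros((height, width))
                kernel[br, bc] = lr
            weights -= kernel[:, :, None] * diff
            for task, block in outputs.items():
                target = np.zeros(block.shape[2])
                target[encoded[task][i]] = 1.0
                block += kernel[:, :, None] * (target[None, None, :] - block)
    grid = SOMGrid(
        width=width,
        height=height,
        weights=weights,
        toroidal=True,
        training_params={"epochs": epochs, "learning_rate": list(learning_rate), "radius0": radius0, "seed": seed},
    )
    return CPGNNModel(kohonen=grid, output_layer=outputs, tasks=task_alphabets, epochs=epochs)


def predict_cpgnn(model: CPGNNModel, x: np.ndarray) -> dict[str, str]:
    """Predicted class per task for one descriptor vector.

    The winning neuron is found in the Kohonen layer; per task the class
    with the largest output entry wins, ties resolving to the
    alphabetically first class.
    """
    br, bc = winner(model.kohonen, x)
    result = {}
    for task, alphabet in model.tasks.items():
        result[task] = alphabet[int(np.argmax(model.output_layer[task][br, bc]))]
    return result


def predict_many(model: CPGNNModel, X: np.ndarray) -> pd.DataFrame:
    """Row-wise :func:`predict_cpgnn` as a label table."""
    rows = [predict_cpgnn(model, x) for x in np.asarray(X, dtype=float)]
    return pd.DataFrame(rows, columns=list(model.tasks))


def crossvalidate_10fold(
    X: np.ndarray,
    Y: pd.DataFrame,
    *,
    grid_spec: tuple[int, int] | None = None,
    epochs: int = 100,
    seed: int = 0,
    n_folds: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Out-of-fold predictions from seeded, chain-type-stratified k-fold CV.

    Returns (true labels, out-of-fold predicted labels), row-aligned
    with ``X``; summarise them with :func:`glycoshift.evaluation.evaluate`.
    Folds are stratified on the coarsest label (chain type) and differ
    in size by at most one.
    """
    from sklearn.model_selection import StratifiedKFold

    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < n_folds:
        raise ValueError(f"need at least {n_folds} objects for {n_folds}-fold CV; consider leave-one-out")
    strata = Y["chain_type"] if "chain_type" in Y.columns else pd.Series(["_"] * n)
    if strata.value_counts().min() < n_folds:
        # a stratum thinner than the fold count cannot be spread over all
        # folds; fall back to unstratified shuffling
        strata = pd.Series(["_"] * n)
    splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    predictions = pd.DataFrame(index=range(n), columns=list(Y.columns), dtype=object)
    for fold, (train_idx, test_idx) in enumerate(splitter.split(X, strata)):
        spec = grid_spec if grid_spec is not None else grid_size_for(len(train_idx))
        model = train_cpgnn(
            X[train_idx], Y.iloc[train_idx].reset_index(drop=True), spec, epochs=epochs, seed=seed + fold
        )
        fold_pred = predict_many(model, X[test_idx])
        for j, row_idx in enumerate(test_idx):
            predictions.iloc[row_idx] = fold_pred.iloc[j]
    return Y.reset_index(drop=True), predictions
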