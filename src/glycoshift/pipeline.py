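"""End-to-end driver: simulate/load -> encode -> split -> train -> evaluate.

The pipeline reproduces the study design: an approximately 3:1
train/test partition chosen on a Kohonen map, per-task random forests
and CART trees plus one joint counterpropagation network, internal
validation matching each method (out-of-bag for the forest, 10-fold
cross-validation for the network, resubstitution of the CV-pruned tree
for CART, with the tree's cross-validated variant reported separately),
and external validation on the held-out test set.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import cpgnn as cpgnn_mod
from . import trees as trees_mod
from .encoding import descriptor_matrix
from .evaluation import TaskReport, compare, evaluate, reports_frame
from .records import TASKS, TASK_NAMES, SpectrumRecord, labels_frame, read_dataset, write_dataset
from .simulate import default_increment_model, generate_dataset
from .som import diversity_split

__all__ = ["run_pipeline", "train_task_models", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _labels(records: Sequence[SpectrumRecord]) -> pd.DataFrame:
    return labels_frame(records).reset_index(drop=True)


def train_task_models(
    X: np.ndarray,
    Y: pd.DataFrame,
    method: str,
    seed: int,
    tasks: Sequence[str] | None = None,
    **params,
):
    """Fit one model per task (``rf``/``cart``) or one joint model (``cpgnn``)."""
    tasks = list(tasks or TASK_NAMES)
    if method == "cpgnn":
        return cpgnn_mod.train_cpgnn(X, Y[tasks], seed=seed, tasks={t: TASKS[t] for t in tasks}, **params)
    models = {}
    for i, task in enumerate(tasks):
        task_seed = seed + 1000 * i
        if method == "rf":
            models[task] = trees_mod.train_rf(X, list(Y[task]), seed=task_seed, classes=TASKS[task], task=task, **params)
        elif method == "cart":
            models[task] = trees_mod.train_cart(X, list(Y[task]), seed=task_seed, classes=TASKS[task], task=task, **params)
        else:
            raise ValueError(f"unknown method {method!r}")
    return models


def _predict_frame(method: str, models, X: np.ndarray, tasks: Sequence[str]) -> pd.DataFrame:
    if method == "cpgnn":
        return cpgnn_mod.predict_many(models, X)[list(tasks)]
    return pd.DataFrame({task: models[task].predict(X) for task in tasks})


def run_pipeline(config: Mapping, out_dir: str | Path) -> dict:
    """Run the configured experiment; returns {name: artifact path}.

    ``config`` keys (all optional except one of ``dataset.path`` /
    ``dataset.simulate``)::

        seed: int
        dataset: {path: file} | {simulate: {n, n_di, n_tri, noise_sd}}
        split: {n_test: int}          # omit for internal-validation only
        methods: [rf, cart, cpgnn]
        tasks: [ano_f, ...]
        rf: {n_trees, mtry} / cart: {min_split, complexity} / cpgnn: {epochs}
        save_models: bool
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    log_lines: list[str] = []
    seed = int(config.get("seed", 0))
    t0 = time.perf_counter()
    config_hash = hashlib.sha256(json.dumps(_jsonable(config), sort_keys=True).encode()).hexdigest()[:16]
    log_lines.append(f"seed={seed} config_hash={config_hash}")

    stage = "dataset"
    try:
        ds_cfg = dict(config.get("dataset", {}))
        if "path" in ds_cfg:
            records = read_dataset(ds_cfg["path"])
        else:
            sim = dict(ds_cfg.get("simulate", {}))
            n = int(sim.get("n", 273))
            balance = {k: sim[k] for k in ("n_di", "n_tri", "quotas") if k in sim}
            model = default_increment_model(noise_sd=float(sim.get("noise_sd", 0.3)))
            dataset = generate_dataset(n, balance, model, seed=seed)
            records = dataset.records
            artifacts["dataset"] = out_dir / "dataset.tsv"
            write_dataset(records, artifacts["dataset"])
        log_lines.append(f"dataset: {len(records)} records")
    except Exception as exc:  # noqa: BLE001 - stage name is part of the contract
        raise PipelineError(stage, exc) from exc

    stage = "split"
    try:
        split_cfg = dict(config.get("split", {}))
        n_test = int(split_cfg.get("n_test", 0))
        if n_test > 0:
            train_ids, test_ids = diversity_split(records, n_test, seed=seed)
            by_id = {r.id: r for r in records}
            train_records = [by_id[i] for i in train_ids]
            test_records = [by_id[i] for i in test_ids]
            artifacts["train"] = out_dir / "train.tsv"
            artifacts["test"] = out_dir / "test.tsv"
            write_dataset(train_records, artifacts["train"])
            write_dataset(test_records, artifacts["test"])
        else:
            train_records, test_records = list(records), []
        log_lines.append(f"split: {len(train_records)} train / {len(test_records)} test")
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    stage = "encode"
    try:
        X_train, _ = descriptor_matrix(train_records)
        Y_train = _labels(train_records)
        if test_records:
            X_test, _ = descriptor_matrix(test_records)
            Y_test = _labels(test_records)
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    methods = list(config.get("methods", ["rf", "cart", "cpgnn"]))
    tasks = list(config.get("tasks", TASK_NAMES))
    report_sets: dict[str, dict[str, dict[str, TaskReport]]] = {}
    for method in methods:
        stage = f"train:{method}"
        try:
            t_start = time.perf_counter()
            params = dict(config.get(method, {}))
            models = train_task_models(X_train, Y_train, method, seed=seed, tasks=tasks, **params)
            internal = _internal_reports(method, models, X_train, Y_train, tasks, seed, params)
            by_set = {"internal": internal}
            if method == "cart":
                by_set["internal_cv"] = _cart_cv_reports(X_train, Y_train, tasks, seed, params)
            if test_records:
                pred = _predict_frame(method, models, X_test, tasks)
                by_set["test"] = evaluate(Y_test[tasks], pred, {t: TASKS[t] for t in tasks})
            report_sets[method] = by_set
            if config.get("save_models", False):
                artifacts[f"model:{method}"] = _save_models(out_dir, method, models)
            log_lines.append(f"{method}: trained in {time.perf_counter() - t_start:.1f}s")
        except Exception as exc:
            raise PipelineError(stage, exc) from exc

    stage = "report"
    try:
        for method, by_set in report_sets.items():
            for set_name, reports in by_set.items():
                path = out_dir / f"report_{method}_{set_name}.tsv"
                reports_frame(reports).to_csv(path, sep="\t", index=False)
                artifacts[f"report:{method}:{set_name}"] = path
        table = compare(report_sets)
        path = out_dir / "comparison.tsv"
        table.to_csv(path, sep="\t")
        artifacts["comparison"] = path
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    log_lines.append(f"total {time.perf_counter() - t0:.1f}s")
    log_path = out_dir / "run.log"
    log_path.write_text("\n".join(log_lines) + "\n")
    artifacts["log"] = log_path
    return artifacts


def _internal_reports(method, models, X, Y, tasks, seed, params) -> dict[str, TaskReport]:
    if method == "rf":
        reports = {}
        for task in tasks:
            report, _ = trees_mod.oob_report(models[task], X, list(Y[task]))
            reports[task] = report
        return reports
    if method == "cpgnn":
        y_true, y_pred = cpgnn_mod.crossvalidate_10fold(X, Y[tasks], seed=seed, epochs=int(params.get("epochs", 100)))
        return evaluate(y_true, y_pred, {t: TASKS[t] for t in tasks})
    # cart: resubstitution of the CV-pruned tree
    pred = _predict_frame(method, models, X, tasks)
    return evaluate(Y[tasks], pred, {t: TASKS[t] for t in tasks})


def _cart_cv_reports(X, Y, tasks, seed, params) -> dict[str, TaskReport]:
    """Out-of-fold CART predictions (10-fold, seeded) per task."""
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    order = rng.permutation(n)
    folds = np.array_split(order, 10) if n >= 10 else [np.arange(n)]
    pred = pd.DataFrame(index=range(n), columns=tasks, dtype=object)
    for fold in folds:
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        if not mask.any():
            mask[:] = True
        for task in tasks:
            model = trees_mod.train_cart(
                X[mask], list(Y[task][mask]), seed=seed, classes=TASKS[task], task=task, **params
            )
            pred.loc[fold, task] = model.predict(X[fold])
    return evaluate(Y[tasks], pred, {t: TASKS[t] for t in tasks})


def _save_models(out_dir: Path, method: str, models) -> Path:
    models_dir = out_dir / "models"
    models_dir.mkdir(exist_ok=True)
    if method == "cpgnn":
        path = models_dir / "cpgnn.json"
        path.write_text(dumps_model(cpgnn_to_dict(models)))
        return path
    for task, model in models.items():
        (models_dir / f"{method}_{task}.json").write_text(dumps_model(model.to_dict()))
    return models_dir


def dumps_model(data: dict) -> str:
    return json.dumps(data, sort_keys=True, separators=(",", ":"))


def cpgnn_to_dict(model: cpgnn_mod.CPGNNModel) -> dict:
    return {
        "kind": "cpgnn",
        "tasks": {t: list(a) for t, a in model.tasks.items()},
        "epochs": model.epochs,
        "grid": {
            "width": model.kohonen.width,
            "height": model.kohonen.height,
            "toroidal": model.kohonen.toroidal,
            "weights": model.kohonen.weights.tolist(),
            "training_params": _jsonable(model.kohonen.training_params),
        },
        "output_layer": {t: block.tolist() for t, block in model.output_layer.items()},
    }


def cpgnn_from_dict(data: dict) -> cpgnn_mod.CPGNNModel:
    from .som import SOMGrid

    grid = SOMGrid(
        width=data["grid"]["width"],
        height=data["grid"]["height"],
        weights=np.array(data["grid"]["weights"], dtype=float),
        toroidal=data["grid"]["toroidal"],
        training_params=dict(data["grid"].get("training_params", {})),
    )
    return cpgnn_mod.CPGNNModel(
        kohonen=grid,
        output_layer={t: np.array(b, dtype=float) for t, b in data["output_layer"].items()},
        tasks={t: tuple(a) for t, a in data["tasks"].items()},
        epochs=int(data["epochs"]),
    )


def load_model(path: str | Path):
    data = json.loads(Path(path).read_text())
    kind = data.get("kind")
    if kind == "rf":
        return trees_mod.ForestModel.from_dict(data)
    if kind == "cart":
        return trees_mod.CARTModel.from_dict(data)
    if kind == "cpgnn":
        return cpgnn_from_dict(data)
    raise ValueError(f"unknown model kind {kind!r} in {path}")


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
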