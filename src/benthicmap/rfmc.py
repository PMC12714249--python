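"""Monte-Carlo random-forest ensemble over repeated 70/30 splits.

Each simulation re-seeds the pseudorandom stream, splits the ground-truth
table into training (70%) and external validation (30%) sets, fits a random
forest (ntree=215, mtry=6, nodesize=1, unlimited maxnodes by default), and
records:

* training accuracy — the complement of the out-of-bag error (1 - E_OOB);
* validation accuracy on the held-out 30%;
* one-vs-rest precision / recall / F1 per habitat class;
* permutation importance as Mean Decrease in Accuracy, computed per tree on
  its own out-of-bag cases and averaged over trees, both model-wide and
  restricted to each class's cases, in percentage points (unscaled).

Cross-simulation means and standard deviations summarize the ensemble; the
per-class F1 reported is the mean of per-simulation F1s, not the F1 of mean
precision and recall (the two differ, and the convention matters when
comparing tables).

The forest learner itself is scikit-learn's RandomForestClassifier; this
module owns the Monte-Carlo protocol, the assessment statistics and the
out-of-bag permutation importance around it.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import precision_recall_fscore_support

from .stack import PredictorStack

__all__ = [
    "RFParams",
    "MCParams",
    "SimulationResult",
    "EnsembleSummary",
    "extract_training_table",
    "run_monte_carlo",
    "summarize_ensemble",
    "tune_hyperparameters",
    "oob_indices",
]

META_COLUMNS = ("class", "drop_id")


@dataclass
class RFParams:
    ntree: int = 215
    mtry: int = 6
    nodesize: int = 1
    maxnodes: int | None = None

    def __post_init__(self) -> None:
        if self.ntree < 1:
            raise ValueError("ntree must be >= 1")
        if self.mtry < 1:
            raise ValueError("mtry must be >= 1")


@dataclass
class MCParams:
    n_sim: int = 175
    train_fraction: float = 0.70
    base_seed: int = 0
    stratified: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.n_sim < 1:
            raise ValueError("n_sim must be >= 1")


@dataclass
class SimulationResult:
    sim_id: int
    train_accuracy: float
    validation_accuracy: float
    per_class: pd.DataFrame  # index=class, columns=precision/recall/f1
    importance: pd.DataFrame  # index=predictor, columns=classes+"model"
    model: RandomForestClassifier
    feature_names: list[str]


@dataclass
class EnsembleSummary:
    mean_train_accuracy: float
    sd_train_accuracy: float
    mean_validation_accuracy: float
    sd_validation_accuracy: float
    overfit_gap: float
    per_class: pd.DataFrame
    importance: pd.DataFrame  # sorted by model-wide importance, descending
    n_sim: int = 0


def extract_training_table(
    stack: PredictorStack, truth: pd.DataFrame
) -> pd.DataFrame:
    """Join ground-truth observations to predictor values at their cells.

    Observations falling on masked or nodata cells are dropped (with a
    warning carrying the count); everything else becomes one row of
    predictors + class + drop_id.
    """
    rows, cols = stack.shape
    r = truth["row"].to_numpy()
    c = truth["col"].to_numpy()
    if ((r < 0) | (r >= rows) | (c < 0) | (c >= cols)).any():
        raise ValueError("ground-truth cells outside the predictor grid")

    flat = r * cols + c
    keep = stack.mask.ravel()[flat]
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} observations on masked cells", stacklevel=2
        )
    flat = flat[keep]
    if flat.size == 0:
        raise ValueError("no ground-truth observations on valid cells")

    table = pd.DataFrame(stack.matrix(flat), columns=stack.names)
    table["class"] = truth["class"].to_numpy()[keep]
    table["drop_id"] = truth["drop_id"].to_numpy()[keep]
    return table


def feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLUMNS]


def oob_indices(tree, n_samples: int) -> np.ndarray:
    """Out-of-bag row indices for one tree of a fitted forest.

    The bootstrap is reconstructed from the tree's own seed with the same
    draw the bagging implementation uses (n draws with replacement from n
    rows); rows never drawn are out of bag.
    """
    sampled = np.random.RandomState(tree.random_state).randint(
        0, n_samples, n_samples
    )
    mask = np.ones(n_samples, dtype=bool)
    mask[sampled] = False
    return np.flatnonzero(mask)


def _tree_votes(tree, X: np.ndarray) -> np.ndarray:
    """Predicted class indices from one tree, bypassing per-call overhead."""
    proba = tree.tree_.predict(np.ascontiguousarray(X, dtype=np.float32))
    if proba.ndim == 3:  # (n, n_outputs, n_classes) in some versions
        proba = proba[:, 0, :]
    return np.argmax(proba, axis=1)


def _oob_permutation_importance(
    forest: RandomForestClassifier,
    X: np.ndarray,
    y_idx: np.ndarray,
    classes: list[str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Mean Decrease in Accuracy on out-of-bag cases, averaged over trees.

    For each tree and predictor, the predictor's values are shuffled among
    that tree's OOB cases and the drop in OOB accuracy recorded; per-class
    columns restrict the accuracy to that class's cases. Units: percentage
    points.
    """
    n, p = X.shape
    k = len(classes)
    deltas = np.zeros((p, k + 1))
    counts = np.zeros(k + 1)

    for tree in forest.estimators_:
        oob = oob_indices(tree, n)
        if oob.size == 0:
            continue
        X_oob = X[oob]
        y_oob = y_idx[oob]
        base = _tree_votes(tree, X_oob)
        base_hit = base == y_oob

        class_masks = [y_oob == ci for ci in range(k)]
        base_acc = np.empty(k + 1)
        base_acc[k] = base_hit.mean()
        for ci, m in enumerate(class_masks):
            base_acc[ci] = base_hit[m].mean() if m.any() else np.nan

        perm = rng.permutation(oob.size)
        for j in range(p):
            X_perm = X_oob.copy()
            X_perm[:, j] = X_oob[perm, j]
            hit = _tree_votes(tree, X_perm) == y_oob
            acc = np.empty(k + 1)
            acc[k] = hit.mean()
            for ci, m in enumerate(class_masks):
                acc[ci] = hit[m].mean() if m.any() else np.nan
            valid = np.isfinite(base_acc) & np.isfinite(acc)
            deltas[j, valid] += base_acc[valid] - acc[valid]
        valid = np.isfinite(base_acc)
        counts += valid

    with np.errstate(invalid="ignore", divide="ignore"):
        mda = 100.0 * deltas / counts
    return pd.DataFrame(mda, columns=list(classes) + ["model"])


def _split(
    y: np.ndarray, mc: MCParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """One 70/30 split; simple random by default, optionally stratified.

    A simple random draw can, rarely, miss a small class entirely; the
    split is then redrawn with a warning so every class is represented in
    training.
    """
    n = y.size
    classes = np.unique(y)
    if mc.stratified:
        train = []
        for cls in classes:
            idx = np.flatnonzero(y == cls)
            idx = rng.permutation(idx)
            n_train = max(1, round(mc.train_fraction * idx.size))
            train.append(idx[:n_train])
        train_idx = np.sort(np.concatenate(train))
    else:
        for attempt in range(100):
            order = rng.permutation(n)
            train_idx = np.sort(order[: round(mc.train_fraction * n)])
            if np.isin(classes, y[train_idx]).all():
                break
            warnings.warn(
                "a class was absent from the training split; redrawing",
                stacklevel=3,
            )
        else:
            raise RuntimeError("could not draw a split containing all classes")
    val_mask = np.ones(n, dtype=bool)
    val_mask[train_idx] = False
    return train_idx, np.flatnonzero(val_mask)


def run_monte_carlo(
    table: pd.DataFrame,
    rf: RFParams | None = None,
    mc: MCParams | None = None,
) -> list[SimulationResult]:
    """Run the Monte-Carlo ensemble; simulation i seeds every random draw
    (split, forest, permutations) from ``base_seed + i``.
    """
    rf = rf or RFParams()
    mc = mc or MCParams()
    features = feature_columns(table)
    if rf.mtry > len(features):
        raise ValueError(
            f"mtry={rf.mtry} exceeds the {len(features)} available predictors"
        )
    y_labels = table["class"].to_numpy()
    classes = sorted(np.unique(y_labels))
    if len(classes) < 2:
        raise ValueError("training table needs at least two classes")
    counts = pd.Series(y_labels).value_counts()
    if (counts < 2).any():
        raise ValueError("every class needs at least two observations")

    X = table[features].to_numpy(dtype=float)
    class_to_idx = {c: i for i, c in enumerate(classes)}
    y_idx = np.array([class_to_idx[c] for c in y_labels])

    results = []
    for i in range(mc.n_sim):
        seed = mc.base_seed + i
        rng = np.random.default_rng(seed)
        train_idx, val_idx = _split(y_labels, mc, rng)

        forest = RandomForestClassifier(
            n_estimators=rf.ntree,
            max_features=rf.mtry,
            min_samples_leaf=rf.nodesize,
            max_leaf_nodes=rf.maxnodes,
            oob_score=True,
            bootstrap=True,
            random_state=seed,
            n_jobs=1,
        )
        with warnings.catch_warnings():
            # tiny OOB folds can miss a class; the score itself is still defined
            warnings.simplefilter("ignore", UserWarning)
            forest.fit(X[train_idx], y_idx[train_idx])

        train_acc = float(forest.oob_score_)
        pred_val = forest.predict(X[val_idx])
        val_acc = float((pred_val == y_idx[val_idx]).mean())

        prec, rec, f1, _ = precision_recall_fscore_support(
            y_idx[val_idx], pred_val, labels=range(len(classes)), zero_division=0
        )
        per_class = pd.DataFrame(
            {"precision": prec, "recall": rec, "f1": f1}, index=classes
        )

        imp = _oob_permutation_importance(
            forest, X[train_idx], y_idx[train_idx], classes, rng
        )
        imp.index = features

        results.append(
            SimulationResult(
                sim_id=i,
                train_accuracy=train_acc,
                validation_accuracy=val_acc,
                per_class=per_class,
                importance=imp,
                model=forest,
                feature_names=features,
            )
        )
    return results


def summarize_ensemble(results: list[SimulationResult]) -> EnsembleSummary:
    """Cross-simulation means/sds; importances rank-ordered model-wide."""
    if not results:
        raise ValueError("no simulation results to summarize")
    train = np.array([r.train_accuracy for r in results])
    val = np.array([r.validation_accuracy for r in results])

    per_class = (
        pd.concat([r.per_class for r in results])
        .groupby(level=0, sort=True)
        .mean()
    )
    importance = (
        pd.concat([r.importance for r in results])
        .groupby(level=0, sort=False)
        .mean()
        .sort_values("model", ascending=False)
    )
    return EnsembleSummary(
        mean_train_accuracy=float(train.mean()),
        sd_train_accuracy=float(train.std(ddof=1)) if train.size > 1 else 0.0,
        mean_validation_accuracy=float(val.mean()),
        sd_validation_accuracy=float(val.std(ddof=1)) if val.size > 1 else 0.0,
        overfit_gap=float(train.mean() - val.mean()),
        per_class=per_class,
        importance=importance,
        n_sim=len(results),
    )


def tune_hyperparameters(
    table: pd.DataFrame,
    grid: dict[str, list],
    mc: MCParams | None = None,
    base_rf: RFParams | None = None,
) -> pd.DataFrame:
    """Mean +/- sd validation accuracy over a hyperparameter grid.

    ``grid`` maps any of {ntree, mtry, maxnodes, nodesize, n_sim} to the
    values to sweep; the cartesian product is evaluated with a (usually
    reduced) Monte-Carlo run per point, for plateau inspection.
    """
    mc = mc or MCParams()
    base_rf = base_rf or RFParams()
    allowed = {"ntree", "mtry", "maxnodes", "nodesize", "n_sim"}
    unknown = set(grid) - allowed
    if unknown:
        raise ValueError(f"unknown hyperparameters: {sorted(unknown)}")

    rows = []
    keys = list(grid)
    for combo in itertools.product(*(grid[k] for k in keys)):
        setting = dict(zip(keys, combo))
        rf_kwargs = {k: v for k, v in setting.items() if k != "n_sim"}
        rf = RFParams(**{**base_rf.__dict__, **rf_kwargs})
        mc_i = MCParams(**{**mc.__dict__, "n_sim": setting.get("n_sim", mc.n_sim)})
        summary = summarize_ensemble(run_monte_carlo(table, rf, mc_i))
        rows.append(
            {
                **setting,
                "mean_train_accuracy": summary.mean_train_accuracy,
                "mean_validation_accuracy": summary.mean_validation_accuracy,
                "sd_validation_accuracy": summary.sd_validation_accuracy,
            }
        )
    return pd.DataFrame(rows)
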