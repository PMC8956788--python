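"""Tree-ensemble classification of priority classes.

Two classifiers are fitted on the unit-level index variables (surface
area, conservation score Cwt, relative rarity RRw, plus one-hot country
indicators) against the high/low priority label: a random forest whose
features-per-split is tuned by an out-of-bag (OOB) error search, and a
gradient-boosted tree model trained with soft-probability output and
multiclass log-loss.  Both expose variable importances — mean decrease
in accuracy (OOB permutation) and mean decrease in Gini for the forest,
normalized gain for the boosted trees — and partial-dependence curves of
the predicted high-priority probability.

The forest's importances follow the classic OOB-permutation definition:
for each tree, accuracy on its out-of-bag rows is compared with accuracy
after permuting one feature among those rows, and the decreases are
averaged over trees.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split
from sklearn.utils import check_random_state
from xgboost import XGBClassifier

from .errors import AnalysisError

__all__ = [
    "FittedModel",
    "PriorityModelReport",
    "build_features",
    "split_data",
    "fit_random_forest",
    "fit_gradient_boosting",
    "evaluate",
    "partial_dependence",
    "model_report",
]

logger = logging.getLogger(__name__)

POSITIVE_CLASS = "high"
NUMERIC_FEATURES = ("area_km2", "cwt", "rrw")


@dataclass
class FittedModel:
    """A trained classifier plus its feature space and importances."""

    name: str  # "rf" or "gbt"
    estimator: object
    feature_names: list[str]
    classes: list[str]
    importances: pd.DataFrame
    params: dict = field(default_factory=dict)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        pred = np.asarray(self.estimator.predict(X[self.feature_names]))
        if pred.ndim == 2:  # soft-probability output: take the modal class
            pred = pred.argmax(axis=1)
        if np.issubdtype(pred.dtype, np.integer):
            return np.asarray(self.classes)[pred]
        return pred

    def predict_proba_high(self, X: pd.DataFrame) -> np.ndarray:
        proba = self.estimator.predict_proba(X[self.feature_names])
        idx = self.classes.index(POSITIVE_CLASS)
        return proba[:, idx]


def build_features(results: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Feature matrix and label vector from a classified results table.

    Columns are the three numeric index variables followed by one-hot
    country indicators in sorted country order, so the layout is
    deterministic and invariant to row order.
    """
    if len(results) < 2:
        raise AnalysisError("need at least 2 units to build a feature matrix")
    X = results[list(NUMERIC_FEATURES)].astype(float).copy()
    for country in sorted(results["country"].unique()):
        X[f"country_{country}"] = (results["country"] == country).astype(float)
    X.index = range(len(X))
    y = pd.Series(results["priority_class"].to_numpy(), name="priority_class")
    return X, y


def split_data(
    X: pd.DataFrame,
    y: pd.Series,
    train_fraction: float = 0.7,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, pd.Series]:
    """Stratified train/test split, reproducible given ``seed``.

    Stratification keeps the class ratio in both parts; with a heavily
    imbalanced high/low split an unstratified 30% test set can end up
    with a single class, which would make the metrics undefined.
    """
    counts = y.value_counts()
    if len(counts) < 2:
        raise AnalysisError(
            "only one priority class present; add data before fitting models"
        )
    thin = counts[counts < 2]
    if not thin.empty:
        raise AnalysisError(
            f"class(es) {list(thin.index)} have fewer than 2 units; "
            "add data before fitting models"
        )
    return train_test_split(
        X,
        y,
        train_size=train_fraction,
        stratify=y,
        random_state=seed,
        shuffle=True,
    )


def _oob_masks(rf: RandomForestClassifier, n_samples: int) -> list[np.ndarray]:
    """Out-of-bag row mask per tree, reconstructed from each tree's seed."""
    masks = []
    for tree in rf.estimators_:
        rs = check_random_state(tree.random_state)
        inbag = rs.randint(0, n_samples, n_samples)
        mask = np.ones(n_samples, dtype=bool)
        mask[inbag] = False
        masks.append(mask)
    return masks


def _oob_permutation_importance(
    rf: RandomForestClassifier,
    X: np.ndarray,
    y: np.ndarray,
    seed: int,
) -> np.ndarray:
    """Mean decrease in OOB accuracy when each feature is permuted."""
    rng = np.random.default_rng(seed)
    n, p = X.shape
    # Trees inside a fitted forest predict encoded class indices.
    y_enc = np.searchsorted(rf.classes_, y).astype(float)
    decreases = np.zeros(p)
    used_trees = 0
    for tree, mask in zip(rf.estimators_, _oob_masks(rf, n)):
        if not mask.any():
            continue
        used_trees += 1
        Xo, yo = X[mask], y_enc[mask]
        base = np.mean(tree.predict(Xo) == yo)
        for j in range(p):
            perm = rng.permutation(len(Xo))
            Xp = Xo.copy()
            Xp[:, j] = Xo[perm, j]
            decreases[j] += base - np.mean(tree.predict(Xp) == yo)
    if used_trees == 0:
        return decreases
    return decreases / used_trees


def _tune_max_features(
    X: pd.DataFrame,
    y_enc: np.ndarray,
    step_factor: float,
    improve: float,
    seed: int,
    n_estimators: int,
) -> int:
    """OOB search for features-per-split, starting from sqrt(p).

    From the sqrt(p) starting point, candidates are generated by
    repeatedly multiplying (and, in the other direction, dividing) by the
    step factor; each direction continues while the OOB error improves by
    at least the ``improve`` fraction, and the best candidate wins.
    """
    p = X.shape[1]

    def oob_error(m: int) -> float:
        rf = RandomForestClassifier(
            n_estimators=n_estimators,
            max_features=m,
            oob_score=True,
            random_state=seed,
            n_jobs=1,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # few-tree OOB coverage warnings
            rf.fit(X, y_enc)
        return 1.0 - rf.oob_score_

    start = max(1, int(math.sqrt(p)))
    best_m, best_err = start, oob_error(start)
    for direction in (step_factor, 1.0 / step_factor):
        m, err = best_m, best_err
        while True:
            m_next = int(round(m * direction))
            m_next = min(max(m_next, 1), p)
            if m_next == m:
                break
            err_next = oob_error(m_next)
            if err <= 0 or (err - err_next) / err < improve:
                break
            m, err = m_next, err_next
        if err < best_err:
            best_m, best_err = m, err
    return best_m


def fit_random_forest(
    X: pd.DataFrame,
    y: pd.Series,
    n_estimators: int = 500,
    tune_step_factor: float = 2.0,
    improve: float = 0.05,
    seed: int = 0,
    tune: bool = True,
) -> FittedModel:
    """Random-forest priority classifier with OOB-tuned features-per-split.

    Importances exposed per feature: ``mean_decrease_accuracy`` (OOB
    permutation) and ``mean_decrease_gini`` (impurity).
    """
    classes = sorted(pd.unique(y))
    y_enc = y.to_numpy()
    max_features = (
        _tune_max_features(X, y_enc, tune_step_factor, improve, seed, n_estimators)
        if tune
        else max(1, int(math.sqrt(X.shape[1])))
    )
    rf = RandomForestClassifier(
        n_estimators=n_estimators,
        max_features=max_features,
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rf.fit(X, y_enc)
    mda = _oob_permutation_importance(rf, X.to_numpy(float), y_enc, seed)
    importances = pd.DataFrame(
        {
            "feature": list(X.columns),
            "mean_decrease_accuracy": mda,
            "mean_decrease_gini": rf.feature_importances_,
        }
    )
    return FittedModel(
        name="rf",
        estimator=rf,
        feature_names=list(X.columns),
        classes=list(classes),
        importances=importances,
        params={"max_features": max_features, "n_estimators": n_estimators,
                "oob_accuracy": float(rf.oob_score_)},
    )


def fit_gradient_boosting(
    X: pd.DataFrame,
    y: pd.Series,
    n_rounds: int = 100,
    seed: int = 0,
    learning_rate: float = 0.3,
    max_depth: int = 6,
) -> FittedModel:
    """Gradient-boosted trees with soft-probability multiclass objective.

    The two priority classes are trained under ``multi:softprob`` with
    multiclass log-loss as the evaluation metric (equivalent to binary
    log-loss for two classes).  Importance is per-feature gain,
    normalized to sum to 1; features never used in a split score 0.
    """
    classes = sorted(pd.unique(y))
    y_enc = np.searchsorted(np.asarray(classes), y.to_numpy())
    model = XGBClassifier(
        n_estimators=n_rounds,
        objective="multi:softprob",
        num_class=len(classes),
        eval_metric="mlogloss",
        random_state=seed,
        learning_rate=learning_rate,
        max_depth=max_depth,
        tree_method="hist",
        verbosity=0,
        n_jobs=1,
    )
    model.fit(X, y_enc)
    gain = model.get_booster().get_score(importance_type="gain")
    raw = np.array([gain.get(name, 0.0) for name in X.columns], float)
    total = raw.sum()
    norm = raw / total if total > 0 else raw
    importances = pd.DataFrame({"feature": list(X.columns), "gain": norm})
    return FittedModel(
        name="gbt",
        estimator=model,
        feature_names=list(X.columns),
        classes=list(classes),
        importances=importances,
        params={"n_rounds": n_rounds, "learning_rate": learning_rate,
                "max_depth": max_depth},
    )


def evaluate(
    model: FittedModel,
    X_test: pd.DataFrame,
    y_test: pd.Series,
    positive_class: str = POSITIVE_CLASS,
) -> dict[str, float]:
    """Confusion-matrix metrics on held-out data, high priority as positive.

    Returns accuracy, recall (sensitivity), specificity, precision and
    F1.  If the test set contains a single class the undefined metrics
    are reported as NaN with a logged warning.
    """
    if len(X_test) == 0:
        raise AnalysisError("empty test set")
    y_true = np.asarray(y_test)
    y_pred = model.predict(X_test)
    pos = y_true == positive_class
    tp = float(np.sum(pos & (y_pred == positive_class)))
    fn = float(np.sum(pos & (y_pred != positive_class)))
    tn = float(np.sum(~pos & (y_pred != positive_class)))
    fp = float(np.sum(~pos & (y_pred == positive_class)))
    if pos.all() or not pos.any():
        logger.warning("test set contains a single class; some metrics undefined")
    accuracy = (tp + tn) / len(y_true)
    recall = tp / (tp + fn) if tp + fn > 0 else float("nan")
    specificity = tn / (tn + fp) if tn + fp > 0 else float("nan")
    precision = tp / (tp + fp) if tp + fp > 0 else float("nan")
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else float("nan")
    )
    return {
        "accuracy": accuracy,
        "recall": recall,
        "specificity": specificity,
        "precision": precision,
        "f1": f1,
    }


def partial_dependence(
    model: FittedModel,
    X: pd.DataFrame,
    feature: str,
    grid: Sequence[float] | None = None,
    n_grid: int = 20,
) -> pd.DataFrame:
    """Mean predicted high-priority probability as one feature is clamped.

    For each grid value the feature column is set to that value for every
    row of ``X`` and the predicted probabilities are averaged.  The grid
    defaults to ``n_grid`` quantiles of the observed feature values.
    """
    if feature not in model.feature_names:
        raise AnalysisError(f"unknown feature {feature!r}")
    if grid is None:
        grid = np.unique(
            np.quantile(X[feature].to_numpy(float), np.linspace(0, 1, n_grid))
        )
    values = []
    for v in grid:
        Xc = X.copy()
        Xc[feature] = v
        values.append(float(model.predict_proba_high(Xc).mean()))
    return pd.DataFrame({feature: list(grid), "p_high": values})


@dataclass
class PriorityModelReport:
    """Metrics, importances and partial-dependence curves for one model."""

    model_name: str
    metrics: dict[str, float]
    importance: pd.DataFrame
    pd_curves: dict[str, pd.DataFrame]

    def to_dict(self) -> dict:
        return {
            "model_name": self.model_name,
            "metrics": self.metrics,
            "importance": self.importance.to_dict(orient="records"),
            "pd_curves": {
                k: v.to_dict(orient="records") for k, v in self.pd_curves.items()
            },
        }


def model_report(
    model: FittedModel,
    X_test: pd.DataFrame,
    y_test: pd.Series,
    pd_features: Sequence[str] = NUMERIC_FEATURES,
) -> PriorityModelReport:
    """Evaluate a fitted model and bundle metrics, importances and PD curves."""
    return PriorityModelReport(
        model_name=model.name,
        metrics=evaluate(model, X_test, y_test),
        importance=model.importances,
        pd_curves={f: partial_dependence(model, X_test, f) for f in pd_features},
    )
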