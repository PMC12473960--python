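"""The six presence/pseudo-absence learners behind one fit/predict contract.

Each algorithm honours its family contract: GLM is a linear-logit
regression; GAM a smooth additive logit (cubic B-spline basis per
predictor); RF bagged trees; GBM boosted shallow trees; CTA a single
decision tree; MARS a hinge-basis (piecewise-linear) logit.  All return
calibrated-looking probabilities in [0, 1] and are deterministic under a
seed.  Hyperparameters are pinned here rather than tuned per run.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import (GradientBoostingClassifier,
                              RandomForestClassifier)
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import SplineTransformer, StandardScaler
from sklearn.tree import DecisionTreeClassifier

from . import metrics as M
from .bioclim import IndicatorStack
from .occurrences import cv_columns

logger = logging.getLogger(__name__)

ALGORITHMS = ("GLM", "GAM", "RF", "GBM", "CTA", "MARS")


class _HingeBasis:
    """MARS-style hinge expansion: max(0, x-k) and max(0, k-x) at interior
    quantile knots, plus the linear term, per predictor."""

    def __init__(self, n_knots: int = 5):
        self.n_knots = n_knots
        self.knots_: list[np.ndarray] = []

    def fit(self, X: np.ndarray) -> "_HingeBasis":
        qs = np.linspace(0, 1, self.n_knots + 2)[1:-1]
        self.knots_ = [np.unique(np.quantile(X[:, j], qs))
                       for j in range(X.shape[1])]
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        cols = [X]
        for j, knots in enumerate(self.knots_):
            x = X[:, j][:, None]
            cols.append(np.maximum(0.0, x - knots[None, :]))
            cols.append(np.maximum(0.0, knots[None, :] - x))
        return np.hstack(cols)


@dataclass
class FittedModel:
    """One trained learner with its training metadata."""

    algorithm: str
    predictors: list[str]
    pa_set: str = ""
    cv_run: int = -1
    seed: int = 0
    _estimator: object = field(default=None, repr=False)
    _hinge: _HingeBasis | None = field(default=None, repr=False)

    @property
    def key(self) -> str:
        return f"{self.algorithm}_{self.pa_set}_run{self.cv_run:02d}"

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.predictors):
            raise ValueError(
                f"expected {len(self.predictors)} predictors "
                f"{self.predictors}, got {X.shape[1]} columns"
            )
        if self._hinge is not None:
            X = self._hinge.transform(X)
        proba = self._estimator.predict_proba(X)[:, 1]
        return np.clip(proba, 0.0, 1.0)


def fit(
    algorithm: str,
    table: pd.DataFrame,
    predictors: list[str],
    seed: int = 0,
    pa_set: str = "",
    cv_run: int = -1,
) -> FittedModel:
    """Train one algorithm on the labelled rows of a modelling table."""
    if algorithm not in ALGORITHMS:
        raise KeyError(f"unknown algorithm {algorithm!r}")
    missing = [p for p in predictors if p not in table.columns]
    if missing:
        raise KeyError(f"predictors missing from table: {missing}")
    y = table["label"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("training data contain a single class")
    X = table[predictors].to_numpy(dtype=float)

    hinge = None
    if algorithm == "GLM":
        est = make_pipeline(
            StandardScaler(),
            LogisticRegression(C=np.inf, max_iter=5000),
        )
    elif algorithm == "GAM":
        est = make_pipeline(
            SplineTransformer(n_knots=6, degree=3),
            LogisticRegression(C=10.0, max_iter=5000),
        )
    elif algorithm == "RF":
        est = RandomForestClassifier(
            n_estimators=100, min_samples_leaf=5, random_state=seed,
            n_jobs=1,
        )
    elif algorithm == "GBM":
        est = GradientBoostingClassifier(
            n_estimators=100, max_depth=3, learning_rate=0.1,
            random_state=seed,
        )
    elif algorithm == "CTA":
        est = DecisionTreeClassifier(
            max_depth=8, min_samples_leaf=10, random_state=seed,
        )
    else:  # MARS
        hinge = _HingeBasis(n_knots=5).fit(X)
        X = hinge.transform(X)
        est = make_pipeline(
            StandardScaler(),
            LogisticRegression(C=10.0, max_iter=5000),
        )
    est.fit(X, y)
    return FittedModel(algorithm=algorithm, predictors=list(predictors),
                       pa_set=pa_set, cv_run=cv_run, seed=seed,
                       _estimator=est, _hinge=hinge)


def predict_points(model: FittedModel, table: pd.DataFrame) -> np.ndarray:
    """Probabilities for the rows of a modelling table."""
    missing = [p for p in model.predictors if p not in table.columns]
    if missing:
        raise KeyError(f"predictors missing from table: {missing}")
    return model.predict(table[model.predictors].to_numpy(dtype=float))


def predict_raster(model: FittedModel, stack: IndicatorStack) -> np.ndarray:
    """Suitability grid in [0, 1]; NaN where any predictor is missing."""
    missing = [p for p in model.predictors if p not in stack]
    if missing:
        raise KeyError(f"predictors missing from stack: {missing}")
    cols = [stack[p].ravel() for p in model.predictors]
    X = np.column_stack(cols)
    out = np.full(X.shape[0], np.nan)
    valid = np.all(np.isfinite(X), axis=1)
    if valid.any():
        out[valid] = model.predict(X[valid])
    return out.reshape(stack.grid.shape)


def fit_all(
    tables: dict[str, pd.DataFrame],
    predictors: list[str],
    algorithms=ALGORITHMS,
    seed: int = 0,
) -> list[FittedModel]:
    """Fit every algorithm on every pseudo-absence set and CV repeat,
    training on that repeat's 'train' rows."""
    models: list[FittedModel] = []
    for pa_set, table in tables.items():
        for rep_col in cv_columns(table):
            rep = int(rep_col.split("_")[1])
            train = table[table[rep_col] == "train"]
            for algo in algorithms:
                models.append(
                    fit(algo, train, predictors, seed=seed,
                        pa_set=pa_set, cv_run=rep)
                )
    return models


def evaluate_model(
    model: FittedModel,
    table: pd.DataFrame,
) -> list[dict]:
    """Score one fitted model on its calibration (train) and validation
    (test) rows with the five-metric suite.

    The Boyce background is the model's whole pseudo-absence table
    (presences plus absences), per block.
    """
    rep_col = f"cv_{model.cv_run:02d}"
    if rep_col not in table.columns:
        raise KeyError(f"table lacks CV column {rep_col}")
    records: list[dict] = []
    all_pred = predict_points(model, table)
    for block, role in (("calibration", "train"), ("validation", "test")):
        sel = (table[rep_col] == role).to_numpy()
        pred = all_pred[sel]
        y = table["label"].to_numpy()[sel]
        results: dict[str, M.MetricResult] = {}
        try:
            results["TSS"] = M.tss(pred, y)
            results["CSI"] = M.csi(pred, y)
            results["BIAS"] = M.bias_score(pred, y)
            results["AUCroc"] = M.auc_roc(pred, y)
            results["BOYCE"] = M.boyce_index(pred[y == 1], all_pred)
        except M.NonEvaluableError as exc:
            logger.warning("%s %s non-evaluable: %s",
                           model.key, block, exc)
        for name, res in results.items():
            records.append(
                {
                    "model": model.key,
                    "algorithm": model.algorithm,
                    "pa_set": model.pa_set,
                    "cv_run": model.cv_run,
                    "block": block,
                    "metric": name,
                    "value": res.value,
                    "cutoff": res.cutoff,
                    "sensitivity": res.sensitivity,
                    "specificity": res.specificity,
                }
            )
    return records


def evaluate_all(
    models: list[FittedModel],
    tables: dict[str, pd.DataFrame],
) -> pd.DataFrame:
    """Evaluation table over every model, block, and metric."""
    rows = list(itertools.chain.from_iterable(
        evaluate_model(m, tables[m.pa_set]) for m in models
    ))
    return pd.DataFrame(rows)
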