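"""Boyce-filtered mean ensemble: membership, projection, variable
importance, response curves, suitability classes, and binarisation.

The ensemble (EMmean) is the unweighted cell-wise mean of every fitted
model whose validation Boyce index exceeds the inclusion threshold (0.8 by
default), pooled across pseudo-absence sets and cross-validation repeats.
Continuous suitability is reported on an integer 0-1000 scale; four classes
partition it at 250/500/750; the presence/absence map thresholds the
continuous scale at the point where the Boyce predicted-to-expected ratio
first reaches 1 (predicted presences become at least as frequent as
expected by chance).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics as M
from .bioclim import ClassMap, IndicatorStack
from .models import FittedModel, predict_points, predict_raster

logger = logging.getLogger(__name__)

BOYCE_INCLUSION = 0.8

SUITABILITY_CLASSES = [
    ("unsuitable", 0.0, 250.0),
    ("moderate", 250.0, 500.0),
    ("high", 500.0, 750.0),        # reported elsewhere as "considerable"
    ("very-high", 750.0, 1000.001),  # closed above at 1000
]

#: Synonyms between the methods-style and results-style class names.
CLASS_SYNONYMS = {"high": "considerable", "very-high": "high"}


@dataclass
class EnsembleModel:
    members: list[FittedModel]
    member_boyce: dict[str, float] = field(default_factory=dict)
    inclusion_threshold: float = BOYCE_INCLUSION

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble has no members")

    @property
    def predictors(self) -> list[str]:
        return self.members[0].predictors

    def to_manifest(self, path) -> None:
        payload = {
            "inclusion_threshold": self.inclusion_threshold,
            "members": [
                {"key": m.key, "validation_boyce":
                    self.member_boyce.get(m.key)}
                for m in self.members
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def build_ensemble(
    evaluations: pd.DataFrame,
    models: list[FittedModel],
    threshold: float = BOYCE_INCLUSION,
) -> EnsembleModel:
    """Members are all models with validation BOYCE > threshold."""
    val = evaluations[(evaluations["block"] == "validation")
                      & (evaluations["metric"] == "BOYCE")]
    boyce = dict(zip(val["model"], val["value"]))
    members = [m for m in models if boyce.get(m.key, -np.inf) > threshold]
    if not members:
        raise ValueError(
            f"no model exceeds the Boyce inclusion threshold {threshold}; "
            f"best is {max(boyce.values(), default=np.nan):.3f} -- "
            "review the threshold or the model set"
        )
    return EnsembleModel(
        members=members,
        member_boyce={m.key: boyce[m.key] for m in members},
        inclusion_threshold=threshold,
    )


def ensemble_predict_points(em: EnsembleModel, table) -> np.ndarray:
    """Mean member probability (in [0, 1]) for table rows."""
    preds = np.mean([predict_points(m, table) for m in em.members], axis=0)
    return preds


def ensemble_predict(em: EnsembleModel, stack: IndicatorStack) -> np.ndarray:
    """Continuous suitability grid on the integer 0-1000 scale."""
    mean = np.mean([predict_raster(m, stack) for m in em.members], axis=0)
    out = np.rint(mean * 1000.0)
    return np.clip(out, 0.0, 1000.0)


def variable_importance(
    em: EnsembleModel,
    table: pd.DataFrame,
    n_permutations: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation importance: 1 - cor(original, column-shuffled
    predictions), averaged over permutations, normalised to percent."""
    base = ensemble_predict_points(em, table)
    if np.std(base) == 0:
        raise ValueError("constant ensemble predictions; "
                         "importance undefined")
    rows = []
    for name in em.predictors:
        raws = []
        for p in range(n_permutations):
            rng = np.random.default_rng([seed, 31, p])
            shuffled = table.copy()
            shuffled[name] = rng.permutation(
                shuffled[name].to_numpy())
            pred = ensemble_predict_points(em, shuffled)
            if np.std(pred) == 0:
                raws.append(1.0)
                continue
            r = np.corrcoef(base, pred)[0, 1]
            raws.append(1.0 - r)
        rows.append({"indicator": name,
                     "importance_raw": float(np.mean(raws))})
    df = pd.DataFrame(rows)
    df["importance_raw"] = df["importance_raw"].clip(lower=0.0)
    total = df["importance_raw"].sum()
    df["importance_pct"] = (100.0 * df["importance_raw"] / total
                            if total > 0 else 0.0)
    return df.sort_values("importance_pct",
                          ascending=False).reset_index(drop=True)


def response_curves(
    em: EnsembleModel,
    table: pd.DataFrame,
    n_steps: int = 100,
) -> pd.DataFrame:
    """Evaluation-strip response curves: vary one predictor across its
    observed range with all others held at their medians."""
    if len(table) == 0:
        raise ValueError("empty table")
    medians = {p: float(table[p].median()) for p in em.predictors}
    frames = []
    for name in em.predictors:
        lo = float(table[name].min())
        hi = float(table[name].max())
        values = np.linspace(lo, hi, n_steps)
        strip = pd.DataFrame(
            {p: np.full(n_steps, medians[p]) for p in em.predictors}
        )
        strip[name] = values
        pred = ensemble_predict_points(em, strip)
        frames.append(pd.DataFrame(
            {"indicator": name, "value": values, "prediction": pred}
        ))
    return pd.concat(frames, ignore_index=True)


def classify_suitability(continuous: np.ndarray, grid) -> ClassMap:
    """Four suitability classes on the 0-1000 scale (lower-inclusive)."""
    values = np.asarray(continuous, dtype=float)
    codes = np.full(values.shape, -1, dtype=int)
    for i, (_, lo, hi) in enumerate(SUITABILITY_CLASSES):
        codes[(values >= lo) & (values < hi)] = i
    codes[~np.isfinite(values)] = -1
    return ClassMap(codes=codes,
                    classes=[(l, lo, min(hi, 1000.0))
                             for l, lo, hi in SUITABILITY_CLASSES],
                    grid=grid, indicator="suitability")


def binarize(
    continuous: np.ndarray,
    presence_pred: np.ndarray,
    background_pred: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Presence/absence map via the Boyce-optimised threshold.

    The threshold is the smallest value on the 0-1000 grid at which the
    Boyce predicted-to-expected ratio first reaches >= 1.  If P/E never
    reaches 1, fall back to the TSS-maximising cutoff treating the
    background as absences, logged.
    """
    continuous = np.asarray(continuous, dtype=float)
    presence_pred = np.asarray(presence_pred, dtype=float)
    if background_pred is None:
        background_pred = continuous[np.isfinite(continuous)].ravel()
    background_pred = np.asarray(background_pred, dtype=float)
    mids, ratios = M.boyce_windows(presence_pred, background_pred)
    reached = np.nonzero(ratios >= 1.0)[0]
    if len(reached):
        threshold = float(np.clip(np.ceil(mids[reached[0]]), 0.0, 1000.0))
    else:
        logger.warning("Boyce P/E never reaches 1; falling back to the "
                       "TSS-maximising cutoff")
        scores = np.concatenate([presence_pred, background_pred]) / 1000.0
        labels = np.concatenate([np.ones(len(presence_pred), dtype=int),
                                 np.zeros(len(background_pred), dtype=int)])
        threshold = M.tss(scores, labels).cutoff * 1000.0
    binary = np.where(np.isfinite(continuous),
                      (continuous >= threshold).astype(int), 0)
    return binary, threshold
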