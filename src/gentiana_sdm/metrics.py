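"""Model evaluation metrics for presence/pseudo-absence predictions.

Threshold-dependent scores (TSS, CSI, BIAS) are reported at the cutoff that
maximises the metric over the grid {0.000, 0.001, ..., 1.000}, following
common SDM-platform behaviour; the optimal cutoff and the sensitivity/
specificity achieved there are stored alongside the value.  AUC is the
rank-based probability that a presence outscores an absence (ties count
one half).  The continuous Boyce index slides equal-width overlapping
windows across the prediction range and rank-correlates the
predicted-to-expected presence ratio with the window midpoint; it is a
presence-only, rank-invariant measure of calibration across the
suitability gradient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata, spearmanr

CUTOFF_GRID = np.round(np.linspace(0.0, 1.0, 1001), 3)

THRESHOLD_METRICS = ("TSS", "CSI", "BIAS")
ALL_METRICS = ("TSS", "AUCroc", "BOYCE", "BIAS", "CSI")


class NonEvaluableError(ValueError):
    """Raised when a metric is undefined for the given inputs."""


@dataclass(frozen=True)
class ConfusionCounts:
    hits: int
    misses: int
    false_alarms: int
    correct_negatives: int

    @property
    def total(self) -> int:
        return (self.hits + self.misses + self.false_alarms
                + self.correct_negatives)

    @property
    def sensitivity(self) -> float:
        denom = self.hits + self.misses
        return self.hits / denom if denom else np.nan

    @property
    def specificity(self) -> float:
        denom = self.correct_negatives + self.false_alarms
        return self.correct_negatives / denom if denom else np.nan


@dataclass(frozen=True)
class MetricResult:
    metric: str
    value: float
    cutoff: float = np.nan
    sensitivity: float = np.nan
    specificity: float = np.nan


def confusion(predictions, labels, cutoff: float) -> ConfusionCounts:
    """Standard 2x2 counts; presence predicted when score >= cutoff."""
    predictions = np.asarray(predictions, dtype=float)
    labels = np.asarray(labels)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels differ in length")
    if not (0.0 <= cutoff <= 1.0):
        raise ValueError("cutoff must lie in [0, 1]")
    pred_pos = predictions >= cutoff
    pos = labels == 1
    return ConfusionCounts(
        hits=int(np.sum(pred_pos & pos)),
        misses=int(np.sum(~pred_pos & pos)),
        false_alarms=int(np.sum(pred_pos & ~pos)),
        correct_negatives=int(np.sum(~pred_pos & ~pos)),
    )


def tss_from_counts(c: ConfusionCounts) -> float:
    return c.sensitivity + c.specificity - 1.0


def csi_from_counts(c: ConfusionCounts) -> float:
    denom = c.hits + c.misses + c.false_alarms
    return c.hits / denom if denom else np.nan


def bias_from_counts(c: ConfusionCounts) -> float:
    denom = c.hits + c.misses
    return (c.hits + c.false_alarms) / denom if denom else np.nan


_FROM_COUNTS = {
    "TSS": tss_from_counts,
    "CSI": csi_from_counts,
    "BIAS": bias_from_counts,
}


def _check_two_class(labels) -> None:
    labels = np.asarray(labels)
    if not ((labels == 1).any() and (labels == 0).any()):
        raise NonEvaluableError("both labels must be present")


def _optimise_cutoff(predictions, labels, metric: str) -> MetricResult:
    """Scan the cutoff grid and report the metric at its optimum.

    For BIAS the optimum is the cutoff bringing the score closest to 1
    (unbiased); for TSS/CSI it is the maximum.
    """
    _check_two_class(labels)
    predictions = np.asarray(predictions, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())

    # Vectorised confusion counts over the whole cutoff grid.
    pred_pos = predictions[None, :] >= CUTOFF_GRID[:, None]
    hits = (pred_pos & pos[None, :]).sum(axis=1)
    fas = (pred_pos & ~pos[None, :]).sum(axis=1)
    sens = hits / n_pos
    spec = (n_neg - fas) / n_neg
    if metric == "TSS":
        scores = sens + spec - 1.0
        best = int(np.argmax(scores))
    elif metric == "CSI":
        denom = hits + (n_pos - hits) + fas
        scores = np.where(denom > 0, hits / np.maximum(denom, 1), np.nan)
        best = int(np.nanargmax(scores))
    elif metric == "BIAS":
        scores = (hits + fas) / n_pos
        best = int(np.argmin(np.abs(scores - 1.0)))
    else:
        raise KeyError(metric)
    return MetricResult(
        metric=metric,
        value=float(scores[best]),
        cutoff=float(CUTOFF_GRID[best]),
        sensitivity=float(sens[best]),
        specificity=float(spec[best]),
    )


def tss(predictions, labels) -> MetricResult:
    """True Skill Statistic at its maximising cutoff."""
    return _optimise_cutoff(predictions, labels, "TSS")


def csi(predictions, labels) -> MetricResult:
    """Critical Success Index (threat score) at its maximising cutoff."""
    return _optimise_cutoff(predictions, labels, "CSI")


def bias_score(predictions, labels) -> MetricResult:
    """Frequency bias at the cutoff closest to the unbiased value 1."""
    return _optimise_cutoff(predictions, labels, "BIAS")


def auc_roc(predictions, labels) -> MetricResult:
    """Rank-based AUC: P(presence outscores absence), ties count 1/2."""
    _check_two_class(labels)
    predictions = np.asarray(predictions, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    ranks = rankdata(predictions)  # average ranks handle ties
    auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    c = confusion(predictions, labels, 0.5)
    return MetricResult(metric="AUCroc", value=float(auc),
                        cutoff=0.5, sensitivity=c.sensitivity,
                        specificity=c.specificity)


def boyce_windows(
    presence_pred,
    background_pred,
    n_windows: int = 101,
    window_width: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Midpoints and P/E ratios of the sliding Boyce windows.

    Windows are equal-width and overlapping on the *quantile* scale of the
    background predictions: each spans a fixed fraction (default one
    tenth) of the background probability mass rather than of the raw
    prediction range.  Because the window edges are defined through the
    background's empirical CDF, the whole construction -- and hence the
    Boyce index -- is exactly invariant under any strictly increasing
    transform of the predictions, which is the property that makes a
    rank-correlation evaluation metric meaningful.  Window midpoints are
    reported back on the prediction scale (the background quantile at the
    window's mass midpoint).  Windows with zero background mass are
    skipped.
    """
    presence_pred = np.asarray(presence_pred, dtype=float)
    background_pred = np.asarray(background_pred, dtype=float)
    lo, hi = background_pred.min(), background_pred.max()
    if hi <= lo:
        raise NonEvaluableError("all background predictions identical; "
                                "Boyce index undefined")
    if not (0.0 < window_width <= 1.0):
        raise ValueError("window_width is a background-mass fraction "
                         "in (0, 1]")
    bg_sorted = np.sort(background_pred)
    n_bg = len(bg_sorted)
    q_pres = np.searchsorted(bg_sorted, presence_pred,
                             side="right") / n_bg
    q_bg = np.searchsorted(bg_sorted, background_pred,
                           side="right") / n_bg
    starts = np.linspace(0.0, 1.0 - window_width, n_windows)
    mids = np.empty(n_windows)
    ratios = np.empty(n_windows)
    for i, s in enumerate(starts):
        e = s + window_width
        # Closed upper edge on the last window so the maximum is counted.
        if i == n_windows - 1:
            in_p = (q_pres >= s) & (q_pres <= e)
            in_b = (q_bg >= s) & (q_bg <= e)
        else:
            in_p = (q_pres >= s) & (q_pres < e)
            in_b = (q_bg >= s) & (q_bg < e)
        p_frac = in_p.mean()
        e_frac = in_b.mean()
        mids[i] = np.quantile(bg_sorted, s + window_width / 2.0)
        ratios[i] = p_frac / e_frac if e_frac > 0 else np.nan
    keep = np.isfinite(ratios)
    return mids[keep], ratios[keep]


def boyce_index(
    presence_pred,
    background_pred,
    n_windows: int = 101,
    window_width: float = 0.1,
) -> MetricResult:
    """Continuous Boyce index: Spearman correlation between the window
    P/E ratio and the window midpoint."""
    presence_pred = np.asarray(presence_pred, dtype=float)
    if len(presence_pred) < 5:
        raise NonEvaluableError("need at least 5 presence predictions")
    if len(np.asarray(background_pred)) < 20:
        raise NonEvaluableError("need at least 20 background predictions")
    mids, ratios = boyce_windows(presence_pred, background_pred,
                                 n_windows, window_width)
    if len(mids) < 3:
        raise NonEvaluableError("too few evaluable Boyce windows")
    if np.all(ratios == ratios[0]):
        # Constant P/E: no gradient in calibration, correlation undefined.
        return MetricResult(metric="BOYCE", value=0.0)
    rho = spearmanr(mids, ratios).statistic
    return MetricResult(metric="BOYCE", value=float(rho))
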