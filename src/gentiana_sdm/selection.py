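"""Predictor screening: Pearson collinearity filter, manual ecological
exclusions, and iterative variance-inflation-factor (VIF) filtering.

The screening order follows standard SDM practice: pairwise Pearson first
(|r| >= 0.7 excluded), then manual exclusions on ecological grounds, then
iterative VIF (< 5 retained).  Because the literature rarely states which
member of a correlated pair was removed, the Pearson step uses a documented
greedy rule: while any pair exceeds the threshold, one variable of the worst
pair is dropped -- a priority-listed variable is pinned (its partner drops);
otherwise the variable with the larger mean |r| against the remaining
candidates drops, ties breaking in favour of the higher-priority variable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PEARSON_THRESHOLD = 0.7
VIF_THRESHOLD = 5.0

#: Priority ordering used for tie-breaks; the four indicators the screening
#: is expected to keep on ecological grounds come first.
DEFAULT_PRIORITY = ("Io", "TXX_aug", "It", "RR_summer")


@dataclass
class SelectionReport:
    candidates: list[str]
    correlation: pd.DataFrame = None
    dropped_by_correlation: list[dict] = field(default_factory=list)
    dropped_manually: list[str] = field(default_factory=list)
    vif_trace: list[dict] = field(default_factory=list)
    retained: list[str] = field(default_factory=list)
    vif_final: dict[str, float] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "candidates": self.candidates,
            "dropped_by_correlation": self.dropped_by_correlation,
            "dropped_manually": self.dropped_manually,
            "vif_trace": self.vif_trace,
            "retained": self.retained,
            "vif_final": self.vif_final,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _priority_rank(name: str, priority) -> int:
    return priority.index(name) if name in priority else len(priority)


def pearson_filter(
    table: pd.DataFrame,
    candidates: list[str],
    threshold: float = PEARSON_THRESHOLD,
    priority=DEFAULT_PRIORITY,
) -> SelectionReport:
    """Greedy removal of highly correlated candidates (|r| >= threshold)."""
    if len(candidates) < 2:
        raise ValueError("need at least two candidate predictors")
    if len(table) < 3:
        raise ValueError("need at least three rows to estimate correlation")

    report = SelectionReport(candidates=list(candidates))
    survivors = list(candidates)

    # Zero-variance columns have undefined correlation: drop them first.
    for name in list(survivors):
        if np.std(table[name].to_numpy(dtype=float)) == 0.0:
            logger.warning("dropping zero-variance candidate %r", name)
            survivors.remove(name)
            report.dropped_by_correlation.append(
                {"dropped": name, "against": None, "r": np.nan,
                 "reason": "zero variance"}
            )

    corr = table[survivors].corr(method="pearson")
    report.correlation = corr.copy()

    def mean_abs_r(name: str, names: list[str]) -> float:
        others = [n for n in names if n != name]
        if not others:
            return 0.0
        return float(corr.loc[name, others].abs().mean())

    while len(survivors) >= 2:
        sub = corr.loc[survivors, survivors].abs()
        np.fill_diagonal(sub.values, 0.0)
        worst = sub.stack().idxmax()
        if sub.loc[worst] < threshold:
            break
        a, b = worst
        a_pinned, b_pinned = a in priority, b in priority
        if a_pinned != b_pinned:
            # Pinned (ecologically preferred) variables survive their pair.
            drop = b if a_pinned else a
        else:
            ma, mb = mean_abs_r(a, survivors), mean_abs_r(b, survivors)
            if ma != mb:
                drop = a if ma > mb else b
            else:
                # Tie: the variable with the lower priority rank survives.
                drop = b if (_priority_rank(a, priority)
                             < _priority_rank(b, priority)) else a
        keep = b if drop == a else a
        survivors.remove(drop)
        report.dropped_by_correlation.append(
            {"dropped": drop, "against": keep,
             "r": float(corr.loc[a, b]), "reason": "pairwise correlation"}
        )
    report.retained = survivors
    return report


def manual_exclude(report: SelectionReport, names) -> SelectionReport:
    """Remove the listed variables regardless of statistics (idempotent)."""
    for name in names:
        if name not in report.candidates:
            raise KeyError(f"unknown candidate {name!r}")
        if name in report.retained:
            report.retained.remove(name)
        if name not in report.dropped_manually:
            report.dropped_manually.append(name)
    return report


def compute_vif(table: pd.DataFrame, names: list[str]) -> dict[str, float]:
    """VIF_j = 1 / (1 - R^2_j), R^2_j from OLS of j on the other names
    (with intercept).  Perfect collinearity yields +inf."""
    values = table[names].to_numpy(dtype=float)
    n = values.shape[0]
    vifs: dict[str, float] = {}
    for j, name in enumerate(names):
        y = values[:, j]
        X = np.column_stack(
            [np.ones(n)] + [values[:, k] for k in range(len(names))
                            if k != j]
        )
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        if ss_tot == 0.0:
            vifs[name] = np.inf
            continue
        r2 = 1.0 - ss_res / ss_tot
        vifs[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return vifs


def vif_filter(
    table: pd.DataFrame,
    report: SelectionReport,
    threshold: float = VIF_THRESHOLD,
) -> SelectionReport:
    """Iteratively remove the max-VIF survivor while any VIF >= threshold."""
    survivors = list(report.retained)
    if len(survivors) < 2:
        raise ValueError("need at least two surviving candidates for VIF")
    while len(survivors) >= 2:
        vifs = compute_vif(table, survivors)
        worst = max(survivors, key=lambda n: vifs[n])
        if vifs[worst] < threshold:
            break
        survivors.remove(worst)
        report.vif_trace.append({"variable": worst,
                                 "vif": float(vifs[worst])})
    report.retained = survivors
    report.vif_final = compute_vif(table, survivors) if len(
        survivors) >= 2 else {n: 1.0 for n in survivors}
    return report


def select_predictors(
    table: pd.DataFrame,
    candidates: list[str],
    manual: tuple[str, ...] = ("Slope", "TX90P"),
    r_threshold: float = PEARSON_THRESHOLD,
    vif_threshold: float = VIF_THRESHOLD,
    priority=DEFAULT_PRIORITY,
) -> SelectionReport:
    """Full screening pipeline: Pearson, manual exclusions, then VIF."""
    report = pearson_filter(table, candidates, r_threshold, priority)
    manual_exclude(report, [m for m in manual if m in candidates])
    return vif_filter(table, report, vif_threshold)
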