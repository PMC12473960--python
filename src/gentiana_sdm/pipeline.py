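"""End-to-end synthetic study: climate to change maps in one call.

The pipeline mirrors the full analysis sequence: generate terrain and a
multi-member daily climate ensemble under the baseline and perturbed
scenarios; compute per-member indicator stacks and their ensemble means;
derive the known true suitability surface and sample occurrence records
from it; clean, thin, and pair them with prevalence-controlled
pseudo-absence sets; screen predictors; fit and evaluate the six-algorithm
model suite with repeated 80/20 cross-validation; build the Boyce-filtered
mean ensemble; project, classify, and binarise suitability for both
periods; and produce change maps and protected-area reports.

Members are processed one at a time so only two daily cubes (baseline and
future of the same member) are ever in memory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from . import bioclim, change, ensemble, models, occurrences, selection
from .areas import ProtectedArea
from .bioclim import IndicatorStack
from .config import SyntheticConfig
from .synthetic import (ElevationRaster, SyntheticOccurrenceReport,
                        generate_elevation, generate_member_climate,
                        generate_protected_areas, sample_occurrences,
                        true_suitability)

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    config: SyntheticConfig
    elevation: ElevationRaster
    stack_hist: IndicatorStack
    stack_future: IndicatorStack
    truth: np.ndarray
    occurrences_raw: pd.DataFrame
    occurrence_report: SyntheticOccurrenceReport
    cleaning_report: occurrences.CleaningReport
    presences: pd.DataFrame
    tables: dict[str, pd.DataFrame]
    selection: selection.SelectionReport
    models: list[models.FittedModel]
    evaluations: pd.DataFrame
    em: ensemble.EnsembleModel
    suit_hist: np.ndarray
    suit_future: np.ndarray
    binary_hist: np.ndarray
    binary_future: np.ndarray
    threshold: float
    change_map: change.ChangeMap
    importance: pd.DataFrame
    protected_areas: list[ProtectedArea] = field(default_factory=list)

    @property
    def truth_recovery_spearman(self) -> float:
        """Rank agreement between the ensemble suitability map and the
        generator's true suitability surface."""
        a = self.suit_hist.ravel()
        b = self.truth.ravel()
        ok = np.isfinite(a) & np.isfinite(b)
        return float(spearmanr(a[ok], b[ok]).statistic)


def build_indicator_stacks(
    config: SyntheticConfig,
    elevation: ElevationRaster,
) -> tuple[IndicatorStack, IndicatorStack]:
    """Member-streamed ensemble-mean indicator stacks (baseline, future).

    Extreme-day indicators of the future period are referenced against the
    same member's baseline percentiles.
    """
    hist_stacks, future_stacks = [], []
    for m in range(config.n_members):
        logger.info("member %d/%d: generating climate and indicators",
                    m + 1, config.n_members)
        base = generate_member_climate(config, elevation, m, "baseline")
        hist_stacks.append(
            bioclim.compute_indicators(base, scenario="baseline",
                                       period="historical")
        )
        future = generate_member_climate(config, elevation, m, "future")
        future_stacks.append(
            bioclim.compute_indicators(future, reference=base,
                                       scenario="future", period="future")
        )
        del base, future
    stack_hist = bioclim.add_topography(
        bioclim.ensemble_mean(hist_stacks), elevation)
    stack_future = bioclim.add_topography(
        bioclim.ensemble_mean(future_stacks), elevation)
    return stack_hist, stack_future


def run_pipeline(
    config: SyntheticConfig | None = None,
    ratios=occurrences.DEFAULT_RATIOS,
    cv_repeats: int = 10,
    algorithms=models.ALGORITHMS,
) -> PipelineResult:
    if config is None:
        config = SyntheticConfig()
    grid = config.grid

    elevation = generate_elevation(config)
    stack_hist, stack_future = build_indicator_stacks(config, elevation)

    truth = true_suitability(stack_hist, config)
    raw, occ_report = sample_occurrences(truth, config)
    cleaned, clean_report = occurrences.clean(raw, grid)
    presences = occurrences.thin(cleaned, grid)
    logger.info("occurrences: %d raw -> %d clean -> %d thinned",
                len(raw), len(cleaned), len(presences))

    pa_sets = occurrences.generate_pseudo_absences(
        presences, grid, ratios=ratios, seed=config.seed)
    tables = {}
    for r, absences in pa_sets.items():
        table = occurrences.build_pa_table(presences, absences, stack_hist)
        tables[f"pa1to{r}"] = occurrences.split_cv(
            table, repeats=cv_repeats, seed=config.seed)

    candidates = list(stack_hist.names)
    sel = selection.select_predictors(tables["pa1to1"], candidates)
    logger.info("selection retained: %s", sel.retained)

    fitted = models.fit_all(tables, sel.retained,
                            algorithms=algorithms, seed=config.seed)
    evaluations = models.evaluate_all(fitted, tables)
    em = ensemble.build_ensemble(evaluations, fitted)
    logger.info("ensemble members: %d of %d models",
                len(em.members), len(fitted))

    suit_hist = ensemble.ensemble_predict(em, stack_hist)
    suit_future = ensemble.ensemble_predict(em, stack_future)

    pres_rows = occurrences.extract_predictors(
        presences.rename(columns={"longitude": "x", "latitude": "y"}),
        stack_hist.subset(sel.retained),
    )
    pres_pred = ensemble.ensemble_predict_points(em, pres_rows) * 1000.0
    binary_hist, threshold = ensemble.binarize(suit_hist, pres_pred)
    # The calibration-period threshold is applied to the projection too,
    # so change maps compare like with like.
    binary_future = np.where(np.isfinite(suit_future),
                             (suit_future >= threshold).astype(int), 0)

    cmap = change.change_map(binary_hist, binary_future, grid)
    importance = ensemble.variable_importance(
        em, tables["pa1to1"], seed=config.seed)
    areas = generate_protected_areas(config)

    return PipelineResult(
        config=config,
        elevation=elevation,
        stack_hist=stack_hist,
        stack_future=stack_future,
        truth=truth,
        occurrences_raw=raw,
        occurrence_report=occ_report,
        cleaning_report=clean_report,
        presences=presences,
        tables=tables,
        selection=sel,
        models=fitted,
        evaluations=evaluations,
        em=em,
        suit_hist=suit_hist,
        suit_future=suit_future,
        binary_hist=binary_hist,
        binary_future=binary_future,
        threshold=threshold,
        change_map=cmap,
        importance=importance,
        protected_areas=areas,
    )


def summarise(result: PipelineResult) -> dict[str, float]:
    """Headline numbers of one pipeline run."""
    dyn = change.change_percentages(result.change_map, basis="dynamic")
    pa_hist = change.protected_area_report(
        result.binary_hist, result.protected_areas, result.config.grid)
    suitable = pa_hist[pa_hist["category"] == "suitable"]
    em_boyce = float(np.mean(list(result.em.member_boyce.values())))
    top = result.importance.iloc[0]
    return {
        "n_presences_thinned": float(len(result.presences)),
        "truth_recovery_spearman": result.truth_recovery_spearman,
        "ensemble_mean_member_boyce": em_boyce,
        "ensemble_n_members": float(len(result.em.members)),
        "top_importance_indicator_pct": float(top["importance_pct"]),
        "suitable_hist_pct": 100.0 * float(result.binary_hist.mean()),
        "suitable_future_pct": 100.0 * float(result.binary_future.mean()),
        "loss_pct_dynamic": float(dyn["loss"]),
        "stable_pct_dynamic": float(dyn["stable"]),
        "gain_pct_dynamic": float(dyn["gain"]),
        "binarisation_threshold": result.threshold,
        **{
            f"{row.designation}_suitable_hist_pct": float(row.percent)
            for row in suitable.itertuples()
        },
    }
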