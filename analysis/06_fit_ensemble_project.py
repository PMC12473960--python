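"""Fit the six-algorithm model suite over all pseudo-absence sets and
CV repeats, evaluate with the five-metric suite, build the
Boyce-filtered mean ensemble, and project continuous / classed / binary
suitability for both periods.

Model fitting and projection run in one stage so fitted estimators never
need to touch disk.
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, outdir, parse_args, study_config  # noqa: E402

from gentiana_sdm import ensemble as ens  # noqa: E402
from gentiana_sdm import models as mdl  # noqa: E402
from gentiana_sdm import occurrences as occ  # noqa: E402
from gentiana_sdm.rasters import read_stack, write_raster  # noqa: E402


def main() -> None:
    args = parse_args(__doc__)
    config = study_config(args)
    out = outdir("06_ensemble")
    stack_hist = read_stack(RESULTS / "02_indicators" / "historical")
    stack_future = read_stack(RESULTS / "02_indicators" / "future")

    with open(RESULTS / "05_selection" / "selection_report.json") as fh:
        retained = json.load(fh)["retained"]
    print("modelling predictors:", retained)

    tables = {}
    for path in sorted((RESULTS / "04_points").glob("pa_table_*.csv")):
        name = path.stem.replace("pa_table_", "pa")
        tables[name] = pd.read_csv(path)

    fitted = mdl.fit_all(tables, retained, seed=config.seed)
    evaluations = mdl.evaluate_all(fitted, tables)
    evaluations.to_csv(out / "evaluations.csv", index=False)
    val_boyce = evaluations[(evaluations.block == "validation")
                            & (evaluations.metric == "BOYCE")]["value"]
    print(f"fitted {len(fitted)} models; validation Boyce "
          f"median {val_boyce.median():.3f}")

    em = ens.build_ensemble(evaluations, fitted)
    em.to_manifest(out / "ensemble_manifest.json")
    print(f"ensemble: {len(em.members)} members with Boyce > "
          f"{em.inclusion_threshold}")

    table_1to1 = tables["pa1to1"]
    importance = ens.variable_importance(em, table_1to1,
                                         seed=config.seed)
    importance.to_csv(out / "variable_importance.csv", index=False)
    print(importance.to_string(index=False))
    curves = ens.response_curves(em, table_1to1)
    curves.to_csv(out / "response_curves.csv", index=False)

    suit_hist = ens.ensemble_predict(em, stack_hist)
    suit_future = ens.ensemble_predict(em, stack_future)
    write_raster(out / "suitability_hist.tif", suit_hist,
                 stack_hist.grid)
    write_raster(out / "suitability_future.tif", suit_future,
                 stack_hist.grid)
    for period, grid_vals in (("hist", suit_hist),
                              ("future", suit_future)):
        cmap = ens.classify_suitability(grid_vals, stack_hist.grid)
        write_raster(out / f"suitability_classes_{period}.tif",
                     cmap.codes.astype(float), stack_hist.grid)

    presences = pd.read_csv(RESULTS / "04_points"
                            / "presences_thinned.csv")
    pres_rows = occ.extract_predictors(
        presences.rename(columns={"longitude": "x", "latitude": "y"}),
        stack_hist.subset(retained))
    pres_pred = ens.ensemble_predict_points(em, pres_rows) * 1000.0
    binary_hist, threshold = ens.binarize(suit_hist, pres_pred)
    binary_future = np.where(np.isfinite(suit_future),
                             (suit_future >= threshold).astype(int), 0)
    write_raster(out / "binary_hist.tif", binary_hist.astype(float),
                 stack_hist.grid)
    write_raster(out / "binary_future.tif", binary_future.astype(float),
                 stack_hist.grid)
    print(f"Boyce-optimised threshold: {threshold:.0f}/1000; suitable "
          f"area {100 * binary_hist.mean():.1f}% (historical) -> "
          f"{100 * binary_future.mean():.1f}% (future)")
    print(f"outputs in {out}")


if __name__ == "__main__":
    main()
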