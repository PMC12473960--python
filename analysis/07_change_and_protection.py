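"""Detect habitat change between the baseline and perturbed-climate
binary suitability maps, and intersect it with the protected areas.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, outdir, parse_args  # noqa: E402

from gentiana_sdm import change as ch  # noqa: E402
from gentiana_sdm.areas import read_geojson  # noqa: E402
from gentiana_sdm.rasters import read_raster, write_raster  # noqa: E402


def main() -> None:
    args = parse_args(__doc__)
    out = outdir("07_change")
    hist, grid = read_raster(RESULTS / "06_ensemble" / "binary_hist.tif")
    future, _ = read_raster(RESULTS / "06_ensemble"
                            / "binary_future.tif")

    cmap = ch.change_map(hist.astype(int), future.astype(int), grid)
    write_raster(out / "change_map.tif", cmap.codes.astype(float), grid)

    rows = []
    for basis in ("dynamic", "total"):
        pct = ch.change_percentages(cmap, basis=basis)
        for label, value in pct.items():
            rows.append({"basis": basis, "category": label,
                         "percent": value})
    pd.DataFrame(rows).to_csv(out / "change_percentages.csv",
                              index=False)
    dyn = ch.change_percentages(cmap, basis="dynamic")
    print(f"dynamic cells: loss {dyn['loss']:.1f}% / stable "
          f"{dyn['stable']:.1f}% / gain {dyn['gain']:.1f}%")

    areas = read_geojson(RESULTS / "01_simulation"
                         / "protected_areas.geojson")
    reports = []
    for name, layer in (("binary_hist", hist.astype(int)),
                        ("binary_future", future.astype(int))):
        rep = ch.protected_area_report(layer, areas, grid)
        rep.insert(0, "layer", name)
        reports.append(rep)
    rep = ch.protected_area_report(cmap, areas)
    rep.insert(0, "layer", "change")
    reports.append(rep)
    pd.concat(reports).to_csv(out / "protected_area_report.csv",
                              index=False)
    for _, row in reports[0].iterrows():
        if row["category"] == "suitable":
            print(f"{row['designation']}: {row['percent']:.1f}% of "
                  f"{row['n_cells']} cells suitable (historical)")
    print(f"outputs in {out}")


if __name__ == "__main__":
    main()
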