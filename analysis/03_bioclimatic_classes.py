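"""Classify the territory into thermotype and ombrotype horizons.

Reads the historical and future It/Io grids from stage 02, maps them
onto the Rivas-Martinez class tables, and reports per-class area shares
and the distribution of occurrence records across classes.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, outdir, parse_args  # noqa: E402

from gentiana_sdm import bioclim, occurrences  # noqa: E402
from gentiana_sdm.rasters import read_stack, write_raster  # noqa: E402


def main() -> None:
    args = parse_args(__doc__)
    out = outdir("03_bioclimate")
    stage02 = RESULTS / "02_indicators"

    occ = pd.read_csv(stage02 / "occurrences_raw.csv")

    tables = []
    for period in ("historical", "future"):
        stack = read_stack(stage02 / period)
        occ_clean, _ = occurrences.clean(occ, stack.grid)
        for indicator, classify in (
            ("It", bioclim.classify_thermotype),
            ("Io", bioclim.classify_ombrotype),
        ):
            cmap = classify(stack[indicator], stack.grid)
            write_raster(out / f"{indicator}_classes_{period}.tif",
                         cmap.codes.astype(float), stack.grid)
            area = bioclim.area_percentages(cmap)
            occ_pct = bioclim.occurrence_class_distribution(cmap,
                                                            occ_clean)
            for label in area.index:
                tables.append({
                    "period": period, "indicator": indicator,
                    "class": label, "area_pct": area[label],
                    "occurrence_pct": occ_pct.get(label, 0.0),
                })
            top = area.drop("out_of_table").idxmax()
            print(f"{period:10s} {indicator}: dominant class "
                  f"'{top}' ({area[top]:.1f}% of area)")

    pd.DataFrame(tables).to_csv(out / "class_distributions.csv",
                                index=False)
    print(f"outputs in {out}")


if __name__ == "__main__":
    main()
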