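"""Clean and thin the occurrence records, then build the five
prevalence-controlled presence/pseudo-absence tables with extracted
predictors and repeated 80/20 cross-validation assignments.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, outdir, parse_args, study_config  # noqa: E402

from gentiana_sdm import occurrences as occ  # noqa: E402
from gentiana_sdm.rasters import read_stack  # noqa: E402


def main() -> None:
    args = parse_args(__doc__)
    config = study_config(args)
    out = outdir("04_points")
    stack = read_stack(RESULTS / "02_indicators" / "historical")

    raw = pd.read_csv(RESULTS / "02_indicators" / "occurrences_raw.csv")
    cleaned, report = occ.clean(raw, stack.grid)
    presences = occ.thin(cleaned, stack.grid)
    presences.to_csv(out / "presences_thinned.csv", index=False)
    print(f"cleaning: {report.n_input} -> {report.n_retained} "
          f"(dropped {report.n_missing_coords} missing, "
          f"{report.n_duplicates} duplicate, "
          f"{report.n_out_of_domain} out-of-domain)")
    print(f"thinning: {report.n_retained} -> {len(presences)} "
          f"(one per occupied 1 km cell)")

    # The reduced --quick grid cannot host the largest prevalence sets.
    ratios = (1, 3) if args.quick else occ.DEFAULT_RATIOS
    pa_sets = occ.generate_pseudo_absences(presences, stack.grid,
                                           ratios=ratios,
                                           seed=config.seed)
    for r, absences in pa_sets.items():
        table = occ.build_pa_table(presences, absences, stack)
        table = occ.split_cv(table, repeats=10, seed=config.seed)
        table.to_csv(out / f"pa_table_1to{r}.csv", index=False)
        print(f"1:{r} table: {len(table)} rows "
              f"({int(table['label'].sum())} presences, "
              f"{len(absences)} absences)")
    print(f"outputs in {out}")


if __name__ == "__main__":
    main()
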