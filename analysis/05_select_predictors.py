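"""Screen the 16 candidate predictors down to the modelling set:
pairwise Pearson (|r| >= 0.7), manual ecological exclusions (Slope,
TX90P), then iterative VIF (< 5).
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, outdir, parse_args  # noqa: E402

from gentiana_sdm import selection as sel  # noqa: E402
from gentiana_sdm.rasters import read_stack  # noqa: E402


def main() -> None:
    args = parse_args(__doc__)
    out = outdir("05_selection")
    stack = read_stack(RESULTS / "02_indicators" / "historical")
    table = pd.read_csv(RESULTS / "04_points" / "pa_table_1to1.csv")

    report = sel.select_predictors(table, list(stack.names))
    report.to_json(out / "selection_report.json")
    report.correlation.to_csv(out / "correlation_matrix.csv")

    print("dropped by correlation:",
          [d["dropped"] for d in report.dropped_by_correlation])
    print("dropped manually:", report.dropped_manually)
    print("dropped by VIF:", [d["variable"] for d in report.vif_trace])
    print("retained:", report.retained)
    print("final VIFs:", {k: round(v, 2)
                          for k, v in report.vif_final.items()})
    print(f"outputs in {out}")


if __name__ == "__main__":
    main()
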