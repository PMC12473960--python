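"""Compute the bio-ecological indicator stacks for both scenarios.

Streams the climate ensemble member by member, computes the 14
bioclimatic indicators per member (future extremes referenced against
the same member's baseline percentiles), forms the ensemble means, adds
the topographic candidates, and derives the true suitability surface and
the sampled occurrence records.  Writes both indicator stacks (one TIFF
per indicator), truth.tif, and occurrences_raw.csv.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import outdir, parse_args, study_config  # noqa: E402

from gentiana_sdm import synthetic  # noqa: E402
from gentiana_sdm.pipeline import build_indicator_stacks  # noqa: E402
from gentiana_sdm.rasters import write_raster, write_stack  # noqa: E402


def main() -> None:
    args = parse_args(__doc__)
    config = study_config(args)
    out = outdir("02_indicators")

    elevation = synthetic.generate_elevation(config)
    stack_hist, stack_future = build_indicator_stacks(config, elevation)
    write_stack(out / "historical", stack_hist)
    write_stack(out / "future", stack_future)
    for name in ("It", "Io", "RR_summer", "TXX_aug"):
        h = stack_hist[name]
        f = stack_future[name]
        print(f"{name:10s} hist mean {h.mean():8.2f} -> "
              f"future mean {f.mean():8.2f}")

    truth = synthetic.true_suitability(stack_hist, config)
    write_raster(out / "truth.tif", truth, config.grid)

    raw, report = synthetic.sample_occurrences(truth, config)
    raw.to_csv(out / "occurrences_raw.csv", index=False)
    print(f"occurrences: {report.n_valid} valid draws plus "
          f"{report.n_duplicates} duplicates, "
          f"{report.n_out_of_domain} out-of-domain, "
          f"{report.n_missing_coords} missing-coordinate records")
    print(f"outputs in {out}")


if __name__ == "__main__":
    main()
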