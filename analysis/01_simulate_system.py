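"""Generate the synthetic study system: terrain, true suitability
inputs, occurrence records and protected areas.

Writes elevation (TIFF), the raw occurrence CSV (including the planted
dirty records), the protected-area GeoJSON, and a one-member sample of
the daily climate (NetCDF) for inspection.  The full climate ensemble is
regenerated deterministically by later stages, so it is not stored.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import outdir, parse_args, study_config  # noqa: E402

from gentiana_sdm import synthetic  # noqa: E402
from gentiana_sdm.areas import write_geojson  # noqa: E402
from gentiana_sdm.rasters import write_raster  # noqa: E402


def main() -> None:
    args = parse_args(__doc__)
    config = study_config(args)
    out = outdir("01_simulation")

    elevation = synthetic.generate_elevation(config)
    write_raster(out / "elevation.tif", elevation.values, config.grid)
    print(f"elevation: {elevation.values.min():.0f}-"
          f"{elevation.values.max():.0f} m over "
          f"{config.grid_nx}x{config.grid_ny} cells")

    # One year of one member is plenty for inspection; the pipeline
    # regenerates the full ensemble deterministically when needed.
    from dataclasses import replace
    sample = synthetic.generate_member_climate(
        replace(config, n_years=1), elevation, 0, "baseline")
    sample.to_netcdf(out / "climate_member00_baseline_year1.nc")
    print(f"sample climate member: {sample.n_years} years, grid-mean "
          f"tas {sample.tas.mean():.1f} degC, "
          f"pr {sample.pr.mean() * 365:.0f} mm/yr")

    areas = synthetic.generate_protected_areas(config)
    write_geojson(areas, out / "protected_areas.geojson")
    print(f"protected areas: {len(areas)} polygons in 2 designations")

    # Occurrences need the true suitability surface, which needs the
    # indicator stack; stage 02 writes truth.tif and the occurrence CSV.
    print(f"outputs in {out}")


if __name__ == "__main__":
    main()
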