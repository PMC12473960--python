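"""Shared configuration for the analysis drivers.

All numbered scripts read this module: the default study is the full
synthetic system (100 x 100 km at 1 km, nine climate members, 20 years,
1,000 presence draws, seed 42); pass ``--quick`` to any script for a
reduced configuration that runs in seconds.
"""

from __future__ import annotations

import argparse
from pathlib import Path

from gentiana_sdm.config import SyntheticConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"


def parse_args(description: str) -> argparse.Namespace:
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--quick", action="store_true",
                        help="small grid / few members, for a fast pass")
    parser.add_argument("--seed", type=int, default=42)
    return parser.parse_args()


def study_config(args: argparse.Namespace) -> SyntheticConfig:
    if args.quick:
        return SyntheticConfig(grid_nx=40, grid_ny=40, n_members=3,
                               n_years=4, n_presence_draws=400,
                               seed=args.seed)
    return SyntheticConfig(seed=args.seed)


def outdir(name: str) -> Path:
    path = RESULTS / name
    path.mkdir(parents=True, exist_ok=True)
    return path
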