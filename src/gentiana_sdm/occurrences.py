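"""Occurrence-record preparation: cleaning, one-per-cell thinning,
prevalence-controlled pseudo-absence design, predictor extraction, and
repeated stratified cross-validation splits.

Occurrence sets are plain DataFrames with columns
``species, longitude, latitude, source_id`` (coordinates in the local km
frame).  Presence/absence tables carry ``point_id, x, y, label, pa_set`` plus
one column per extracted predictor and one ``cv_XX`` role column per repeat.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bioclim import IndicatorStack
from .grid import GridSpec

logger = logging.getLogger(__name__)

OCCURRENCE_COLUMNS = ["species", "longitude", "latitude", "source_id"]

#: Presence-to-absence prevalence ratios used for the pseudo-absence sets.
DEFAULT_RATIOS = (1, 3, 5, 7, 9)


@dataclass(frozen=True)
class CleaningReport:
    n_input: int
    n_missing_coords: int
    n_duplicates: int
    n_out_of_domain: int
    n_retained: int


def clean(
    raw: pd.DataFrame,
    grid: GridSpec,
) -> tuple[pd.DataFrame, CleaningReport]:
    """Drop records with missing coordinates, exact coordinate duplicates,
    and points outside the domain; report counts per category."""
    if len(raw) == 0:
        raise ValueError("empty occurrence set")
    df = raw.copy()

    finite = (np.isfinite(df["longitude"].to_numpy(dtype=float))
              & np.isfinite(df["latitude"].to_numpy(dtype=float)))
    n_missing = int((~finite).sum())
    df = df[finite]

    dup = df.duplicated(subset=["species", "longitude", "latitude"])
    n_dup = int(dup.sum())
    df = df[~dup]

    inside = grid.contains(df["longitude"].to_numpy(),
                           df["latitude"].to_numpy())
    n_out = int((~inside).sum())
    df = df[inside]

    if len(df) == 0:
        raise ValueError("no occurrence records survive cleaning")
    report = CleaningReport(
        n_input=len(raw),
        n_missing_coords=n_missing,
        n_duplicates=n_dup,
        n_out_of_domain=n_out,
        n_retained=len(df),
    )
    return df.reset_index(drop=True), report


def thin(
    occ: pd.DataFrame,
    grid: GridSpec,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Retain one record per occupied grid cell.

    Deterministic by default: the record with the lowest ``source_id``
    survives.  Pass ``rng`` for randomised retention (SpThin-style).
    """
    iy, ix = grid.point_to_cell(occ["longitude"].to_numpy(),
                                occ["latitude"].to_numpy())
    if np.any(iy < 0):
        raise ValueError("thin() expects cleaned, in-domain records")
    df = occ.copy()
    df["_cell"] = grid.cell_id(iy, ix)
    if rng is None:
        df = df.sort_values(["_cell", "source_id"], kind="stable")
    else:
        df = df.iloc[rng.permutation(len(df))]
    df = df.drop_duplicates(subset="_cell", keep="first")
    return (df.drop(columns="_cell")
            .sort_values("source_id")
            .reset_index(drop=True))


def presence_cells(occ: pd.DataFrame, grid: GridSpec) -> np.ndarray:
    """Sorted unique flat cell ids occupied by the occurrence points."""
    iy, ix = grid.point_to_cell(occ["longitude"].to_numpy(),
                                occ["latitude"].to_numpy())
    return np.unique(grid.cell_id(iy, ix))


def generate_pseudo_absences(
    presences: pd.DataFrame,
    grid: GridSpec,
    ratios=DEFAULT_RATIOS,
    seed: int = 0,
) -> dict[int, pd.DataFrame]:
    """One absence set per prevalence ratio.

    For ratio ``r``, exactly ``r * n_presences`` distinct non-presence
    cells are drawn uniformly without replacement and their centres become
    absence points.  The exclusion zone is exactly the presence-occupied
    cells (plain random sampling, no buffer).
    """
    occupied = presence_cells(presences, grid)
    candidates = np.setdiff1d(np.arange(grid.n_cells), occupied)
    n_pres = len(presences)
    out: dict[int, pd.DataFrame] = {}
    for r in ratios:
        n_abs = r * n_pres
        if n_abs > len(candidates):
            raise ValueError(
                f"ratio 1:{r} needs {n_abs} non-presence cells but only "
                f"{len(candidates)} are available "
                f"(short by {n_abs - len(candidates)})"
            )
        rng = np.random.default_rng([seed, 17, r])
        cells = rng.choice(candidates, size=n_abs, replace=False)
        iy, ix = np.divmod(cells, grid.nx)
        x, y = grid.cell_center(iy, ix)
        out[r] = pd.DataFrame(
            {
                "x": x,
                "y": y,
                "cell": cells,
                "pa_set": f"pa1to{r}",
            }
        )
    return out


def extract_predictors(
    points: pd.DataFrame,
    stack: IndicatorStack,
    x_col: str = "x",
    y_col: str = "y",
) -> pd.DataFrame:
    """Attach the containing cell's indicator values to each point row.

    Rows hitting cells where any indicator is missing are dropped and
    logged; an all-missing result is an error.
    """
    iy, ix = stack.grid.point_to_cell(points[x_col].to_numpy(),
                                      points[y_col].to_numpy())
    if np.any(iy < 0):
        raise ValueError("points outside the grid cannot be extracted")
    df = points.reset_index(drop=True).copy()
    valid = np.ones(len(df), dtype=bool)
    for name in stack.names:
        values = stack[name][iy, ix]
        df[name] = values
        valid &= np.isfinite(values)
    if not valid.all():
        logger.warning("dropping %d rows over missing indicator cells",
                       (~valid).sum())
    if not valid.any():
        raise ValueError("all rows fall on missing indicator cells")
    return df[valid].reset_index(drop=True)


def build_pa_table(
    presences: pd.DataFrame,
    absences: pd.DataFrame,
    stack: IndicatorStack,
) -> pd.DataFrame:
    """Combine presences (label 1) and one absence set (label 0) into a
    modelling table with extracted predictor values."""
    pres = presences.rename(
        columns={"longitude": "x", "latitude": "y"}
    )[["x", "y"]].copy()
    pres["label"] = 1
    absn = absences[["x", "y"]].copy()
    absn["label"] = 0
    table = pd.concat([pres, absn], ignore_index=True)
    table.insert(0, "point_id", np.arange(len(table)))
    table["pa_set"] = absences["pa_set"].iloc[0] if len(absences) else "pa"
    return extract_predictors(table, stack)


def split_cv(
    table: pd.DataFrame,
    train_fraction: float = 0.8,
    repeats: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Add ``cv_00 .. cv_{repeats-1}`` columns with stratified-by-label
    train/test roles; each repeat is an independent random partition."""
    labels = table["label"].to_numpy()
    if (labels == 1).sum() < 10 or (labels == 0).sum() < 10:
        raise ValueError("need at least 10 presences and 10 absences "
                         "for cross-validation")
    out = table.copy()
    for rep in range(repeats):
        rng = np.random.default_rng([seed, 23, rep])
        role = np.empty(len(table), dtype=object)
        for lab in (0, 1):
            idx = np.nonzero(labels == lab)[0]
            perm = rng.permutation(idx)
            n_train = int(round(train_fraction * len(idx)))
            role[perm[:n_train]] = "train"
            role[perm[n_train:]] = "test"
        out[f"cv_{rep:02d}"] = role
    return out


def cv_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c.startswith("cv_")]
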