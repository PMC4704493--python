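"""Screen processing: row-median normalization, replicate aggregation,
z-score standardization, hit calling, and variance/responsiveness summaries.

The processing chain mirrors standard plate-screen practice: raw
luminescence in each plate row is divided by the row median (removing
row/position and, because batch factors are constant within a row, batch
effects), replicates are averaged into a mean-viability matrix, each cell
line's column is standardized to z-scores, and hits are the (mimic, line)
cells at or below the z threshold (default -2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import (MimicAnnotations, ScreenPlate, VarianceProfile,
                        ZScoreMatrix)
from .errors import AnnotationGapError, ConfigError, DataError, DegenerateDataError


# ------------------------------------------------------------- normalization

def normalize_row_median(plate: ScreenPlate) -> ScreenPlate:
    """Divide each well by the median of its plate row.

    After normalization the median of every row is exactly 1; a row whose
    median is 0 is degenerate and rejected.
    """
    values = plate.wells["value"].astype(float)
    medians = values.groupby(plate.wells["row"]).transform("median")
    zero_rows = sorted(plate.wells.loc[medians == 0, "row"].unique())
    if zero_rows:
        raise DegenerateDataError(
            f"plate {plate.plate_id}: zero row median in row(s) {', '.join(zero_rows)}")
    return plate.with_values(values / medians, normalized=True)


# -------------------------------------------------------------- aggregation

def aggregate_replicates(plates: Iterable[ScreenPlate],
                         exclude: Sequence[str] = ()) -> tuple[pd.DataFrame,
                                                               pd.DataFrame,
                                                               pd.DataFrame]:
    """Aggregate normalized plates into per-(mimic, line) statistics.

    Returns ``(mean, sd, n)`` DataFrames (mimics x cell lines): mean
    viability, sample SD across replicates (NaN where fewer than two
    replicates contributed -- flagged missing, never fabricated), and the
    contributing replicate count.  ``exclude`` drops reagents (e.g. the
    negative control) from the output.
    """
    plates = list(plates)
    if not plates:
        raise DataError("no plates to aggregate")
    if not all(p.normalized for p in plates):
        raise DataError("aggregate_replicates expects normalized plates")
    frames = []
    for p in plates:
        f = p.wells[["mimic_id", "value"]].copy()
        f["cell_line"] = p.cell_line
        frames.append(f)
    longf = pd.concat(frames, ignore_index=True)
    if exclude:
        longf = longf[~longf["mimic_id"].isin(set(exclude))]
    grouped = longf.groupby(["mimic_id", "cell_line"])["value"]
    mean = grouped.mean().unstack("cell_line")
    sd = grouped.std(ddof=1).unstack("cell_line")
    n = grouped.size().unstack("cell_line").fillna(0).astype(int)
    sd = sd.where(n >= 2)
    return mean, sd, n


# ------------------------------------------------------------------ z-scores

def compute_zscores(mean_viability: pd.DataFrame, scope: str = "per_line",
                    plate_map: Mapping[str, str] | None = None) -> ZScoreMatrix:
    """Standardize mean viability to z-scores.

    scope="per_line" (default) standardizes each cell-line column over all
    mimics of that line; scope="per_plate" standardizes within
    (plate, line) groups and needs a mimic -> plate map.  Sample SD
    (divisor n-1) throughout.  Groups with < 3 values or zero SD are
    degenerate.
    """
    if scope not in ("per_line", "per_plate"):
        raise ConfigError(f"unknown z-score scope {scope!r}")

    def _standardize(col: pd.Series, label: str) -> pd.Series:
        vals = col.dropna()
        if len(vals) < 3:
            raise DegenerateDataError(f"group {label}: fewer than 3 values")
        sd = vals.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise DegenerateDataError(f"group {label}: zero or undefined SD")
        return (col - vals.mean()) / sd

    if scope == "per_line":
        z = pd.DataFrame({c: _standardize(mean_viability[c], str(c))
                          for c in mean_viability.columns})
    else:
        if plate_map is None:
            raise ConfigError("per_plate scope requires a mimic -> plate map")
        plates = mean_viability.index.map(lambda m: plate_map.get(m))
        if plates.isna().any():
            raise DataError("plate_map does not cover all mimics")
        z = mean_viability.copy()
        for col in z.columns:
            for plate, idx in z.groupby(plates).groups.items():
                z.loc[idx, col] = _standardize(mean_viability.loc[idx, col],
                                               f"{plate}/{col}")
    z.index.name = mean_viability.index.name
    return ZScoreMatrix(z, mean_viability=mean_viability)


# ----------------------------------------------------------------- hit calling

def call_hits(z: ZScoreMatrix, threshold: float = -2.0,
              inclusive: bool = True) -> pd.DataFrame:
    """Return the hit table: one row per (mimic, line) with z at or below
    the threshold (inclusive boundary by default)."""
    if threshold >= 0:
        raise ConfigError(f"hit threshold must be negative, got {threshold}")
    mask = z.z.le(threshold) if inclusive else z.z.lt(threshold)
    hits = z.z.where(mask).stack().rename("z").reset_index()
    hits.columns = ["mimic_id", "cell_line", "z"]
    return hits.sort_values(["mimic_id", "cell_line"]).reset_index(drop=True)


@dataclass
class ResponsivenessSummary:
    """Histogram of hit mimics by responsive-line count.

    ``histogram[i]`` counts hit mimics responsive in exactly i+1 lines;
    ``fraction_private`` is the fraction of hit mimics toxic in only 1 or
    2 lines (None when there are no hits).
    """
    histogram: np.ndarray
    fraction_private: float | None
    max_lines: int
    n_hit_mimics: int


def responsiveness_summary(hits: pd.DataFrame, n_lines: int) -> ResponsivenessSummary:
    if n_lines < 1:
        raise ConfigError("n_lines must be >= 1")
    counts = hits.groupby("mimic_id")["cell_line"].nunique()
    hist = np.zeros(n_lines, dtype=int)
    if counts.empty:
        return ResponsivenessSummary(hist, None, 0, 0)
    if counts.max() > n_lines:
        raise DataError(f"a mimic is responsive in {counts.max()} > n_lines lines")
    for c, k in counts.value_counts().items():
        hist[c - 1] = k
    private = int((counts <= 2).sum())
    return ResponsivenessSummary(hist, private / len(counts),
                                 int(counts.max()), int(len(counts)))


def collapse_unique_mature(hits: pd.DataFrame, ann: MimicAnnotations) -> int:
    """Number of distinct mature sequences among hit mimics."""
    hit_mimics = pd.Index(hits["mimic_id"].unique())
    missing = hit_mimics.difference(ann.mimic_ids)
    if len(missing):
        raise AnnotationGapError(missing)
    return int(ann.table.loc[hit_mimics, "mature_sequence"].nunique())


# ------------------------------------------------------------ variance profile

def _silverman_bandwidth(values: np.ndarray) -> float:
    n = len(values)
    sd = values.std(ddof=1) if n > 1 else 0.0
    iqr = np.subtract(*np.percentile(values, [75, 25]))
    spread = min(sd, iqr / 1.34) if iqr > 0 and sd > 0 else max(sd, iqr / 1.34)
    if spread == 0:  # degenerate (all values equal): narrow kernel around the point
        spread = max(abs(values[0]) * 1e-3, 1e-6)
    return 0.9 * spread * n ** (-1 / 5)


def gaussian_kde_curve(values: np.ndarray, grid_size: int = 512
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian KDE with Silverman bandwidth on a grid spanning the data
    plus 4 bandwidths each side (so the curve integrates to ~1)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise DegenerateDataError("cannot fit a KDE to an empty sample")
    h = _silverman_bandwidth(values)
    grid = np.linspace(values.min() - 4 * h, values.max() + 4 * h, grid_size)
    dens = np.exp(-0.5 * ((grid[:, None] - values[None, :]) / h) ** 2)
    dens = dens.sum(axis=1) / (values.size * h * np.sqrt(2 * np.pi))
    return grid, dens


def variance_profile(mean_viability: pd.DataFrame, within_rep_sd: pd.DataFrame,
                     ann: MimicAnnotations) -> VarianceProfile:
    """The three SD distributions of screen reproducibility plus KDEs.

    Families with a single annotated member carry no within-family SD and
    are skipped; if every family is a singleton the family distribution is
    empty and ``family_defined`` is False.
    """
    across = mean_viability.std(axis=1, ddof=1).rename("across_panel_sd")

    fam = ann.families().reindex(mean_viability.index)
    if fam.isna().any():
        raise AnnotationGapError(mean_viability.index[fam.isna()])
    sizes = fam.value_counts()
    multi = sizes[sizes >= 2].index
    fam_records = {}
    for family in multi:
        members = mean_viability.loc[fam[fam == family].index]
        for line in members.columns:
            fam_records[(family, line)] = members[line].std(ddof=1)
    family_sd = pd.Series(fam_records, name="family_sd", dtype=float)
    family_defined = len(family_sd) > 0
    if family_defined:
        family_sd.index = pd.MultiIndex.from_tuples(family_sd.index,
                                                    names=["family_id", "cell_line"])

    within = within_rep_sd.to_numpy().ravel()
    within = within[np.isfinite(within)]

    kde = {"across_panel": gaussian_kde_curve(across.to_numpy()),
           "within_replicate": gaussian_kde_curve(within)}
    if family_defined:
        kde["family"] = gaussian_kde_curve(family_sd.to_numpy())
    return VarianceProfile(across, family_sd, within, kde, family_defined)
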