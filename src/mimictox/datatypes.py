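"""Shared domain containers for the screen-analysis pipeline.

The central in-memory objects are thin dataclasses around pandas
structures: a :class:`ScreenPlate` is one physical 96-well plate (one
cell line, one replicate), a :class:`ZScoreMatrix` is the mimics x
cell-lines standardized viability matrix that every downstream stage
consumes, and a :class:`PhenocopyPanel` bundles one mimic toxicity
profile with per-gene siRNA toxicity profiles from two independent
reagent pools.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, IntegrityError

#: Reserved identifier for the negative-control mimic.
NEGATIVE_CONTROL = "miR-NC"

WELL_COLUMNS = ("plate_id", "cell_line", "replicate", "row", "column",
                "mimic_id", "raw_lum")


@dataclass
class ScreenPlate:
    """One plate of luminescence wells for a single (cell line, replicate).

    ``wells`` holds columns ``row`` (letter label), ``column`` (int >= 1),
    ``mimic_id`` and ``value``.  ``value`` is raw luminescence until
    :func:`mimictox.screen.normalize_row_median` converts it to relative
    viability (``normalized`` flips to True).
    """

    plate_id: str
    cell_line: str
    replicate: int
    wells: pd.DataFrame
    normalized: bool = False

    def __post_init__(self):
        if self.replicate < 1:
            raise DataError(f"replicate must be >= 1, got {self.replicate}")
        missing = {"row", "column", "mimic_id", "value"} - set(self.wells.columns)
        if missing:
            raise DataError(f"plate {self.plate_id}: wells missing columns {sorted(missing)}")
        dup = self.wells.duplicated(subset=["row", "column"])
        if dup.any():
            coords = self.wells.loc[dup, ["row", "column"]].itertuples(index=False)
            raise IntegrityError(
                f"plate {self.plate_id} replicate {self.replicate}: duplicate wells "
                + ", ".join(f"{r}{c}" for r, c in coords))
        if (self.wells["value"] < 0).any():
            raise DataError(f"plate {self.plate_id}: negative luminescence")

    @property
    def rows(self) -> list[str]:
        return sorted(self.wells["row"].unique())

    def with_values(self, values: pd.Series, normalized: bool = True) -> "ScreenPlate":
        wells = self.wells.copy()
        wells["value"] = values
        return ScreenPlate(self.plate_id, self.cell_line, self.replicate,
                           wells, normalized=normalized)


@dataclass
class MimicAnnotations:
    """Mature sequence, seed and seed-family annotation per mimic.

    The seed is the sub-sequence of the mature strand in the configured
    window (1-based positions, default 2-8); mimics sharing a seed share a
    family.
    """

    table: pd.DataFrame  # index mimic_id; columns mature_sequence, seed, family_id
    seed_window: tuple[int, int] = (2, 8)

    ALPHABET = frozenset("ACGU")

    @classmethod
    def from_sequences(cls, sequences: pd.Series | dict,
                       seed_window: tuple[int, int] = (2, 8)) -> "MimicAnnotations":
        seq = pd.Series(dict(sequences) if not isinstance(sequences, pd.Series) else sequences,
                        name="mature_sequence").astype(str)
        lo, hi = seed_window
        if not (1 <= lo <= hi):
            raise ConfigError(f"invalid seed window {seed_window}")
        bad = [m for m, s in seq.items() if not set(s) <= cls.ALPHABET or len(s) < hi]
        if bad:
            raise DataError(f"invalid mature sequences for: {', '.join(map(str, bad))}")
        seeds = seq.str[lo - 1:hi]
        table = pd.DataFrame({
            "mature_sequence": seq,
            "seed": seeds,
            "family_id": "fam-" + seeds,
        })
        table.index.name = "mimic_id"
        return cls(table, seed_window)

    def __post_init__(self):
        if self.table.index.has_duplicates:
            raise IntegrityError("duplicate mimic_id in annotations")
        lo, hi = self.seed_window
        expected = self.table["mature_sequence"].str[lo - 1:hi]
        if not (expected == self.table["seed"]).all():
            raise IntegrityError("seed does not match the configured window of mature_sequence")

    @property
    def mimic_ids(self) -> pd.Index:
        return self.table.index

    def families(self) -> pd.Series:
        """mimic_id -> family_id."""
        return self.table["family_id"]


@dataclass
class ZScoreMatrix:
    """Standardized mean-viability matrix, mimics x cell lines."""

    z: pd.DataFrame
    mean_viability: pd.DataFrame | None = None

    def __post_init__(self):
        if self.z.index.has_duplicates or self.z.columns.has_duplicates:
            raise IntegrityError("duplicate mimic or cell-line labels in z matrix")
        if self.z.index.isna().any() or self.z.columns.isna().any():
            raise DataError("missing mimic/cell-line labels")
        if self.mean_viability is not None:
            if (not self.mean_viability.index.equals(self.z.index)
                    or not self.mean_viability.columns.equals(self.z.columns)):
                raise DataError("mean_viability labels do not match z labels")

    @property
    def mimic_ids(self) -> pd.Index:
        return self.z.index

    @property
    def cell_lines(self) -> pd.Index:
        return self.z.columns


@dataclass
class PhenocopyPanel:
    """A mimic toxicity profile plus per-gene siRNA profiles in two pools.

    ``gene_profiles`` maps pool number (1, 2) to a genes x cell-lines
    relative-viability DataFrame; both pools must cover the identical gene
    set and the full cell-line panel.  ``index_line`` is the sensitive
    line in which the stage-1 viability filter is evaluated.
    """

    cell_lines: list[str]
    mimic_profile: pd.Series
    gene_profiles: dict[int, pd.DataFrame]
    index_line: str

    def __post_init__(self):
        lines = pd.Index(self.cell_lines)
        if self.index_line not in lines:
            raise DataError(f"index_line {self.index_line!r} not in cell_lines")
        if not self.mimic_profile.index.equals(lines):
            raise DataError("mimic_profile is not aligned to cell_lines")
        if set(self.gene_profiles) != {1, 2}:
            raise DataError("gene_profiles must have exactly pools 1 and 2")
        g1, g2 = self.gene_profiles[1], self.gene_profiles[2]
        if not g1.index.equals(g2.index):
            raise DataError("the two pools cover different gene sets")
        for pool, g in self.gene_profiles.items():
            if not g.columns.equals(lines):
                raise DataError(f"pool {pool} profiles not aligned to cell_lines")

    @property
    def genes(self) -> pd.Index:
        return self.gene_profiles[1].index


@dataclass
class VarianceProfile:
    """Three screen-reproducibility SD distributions with their KDEs.

    * ``across_panel_sd`` - per mimic, SD of mean viability across the
      cell-line panel (total phenotypic variation).
    * ``family_sd`` - per (seed family, cell line) with >= 2 members, SD of
      member viabilities (family coherence); empty when every family is a
      singleton (``family_defined`` False).
    * ``within_replicate_sd`` - per (mimic, line), SD across replicates
      (technical noise).

    Each KDE is a (grid, density) pair integrating to ~1.
    """

    across_panel_sd: pd.Series
    family_sd: pd.Series
    within_replicate_sd: np.ndarray
    kde: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    family_defined: bool = True


def validate_survival(records: pd.DataFrame) -> pd.DataFrame:
    """Check a survival cohort table (sample_id, time, event, expression)."""
    missing = {"sample_id", "time", "event", "expression"} - set(records.columns)
    if missing:
        raise DataError(f"survival table missing columns {sorted(missing)}")
    if (records["time"] < 0).any():
        raise DataError("negative survival time")
    if records["sample_id"].duplicated().any():
        raise IntegrityError("duplicate sample_id in survival cohort")
    if not records["event"].isin([0, 1, True, False]).all():
        raise DataError("event must be 0/1")
    return records
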