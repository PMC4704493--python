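"""Delimited-table readers/writers and GraphML cluster-network export.

All tables are UTF-8 delimited text, TSV by default ("." decimal); CSV is
accepted via ``dialect="csv"``.  Empty cells and ``NA`` are read as
missing.  Readers and writers are inverse pairs on valid files.
"""

from __future__ import annotations

import os
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import (WELL_COLUMNS, MimicAnnotations, ScreenPlate,
                        ZScoreMatrix, validate_survival)
from .errors import ConfigError, DataError, IntegrityError, ParseError, SchemaError

NA_REP = "NA"
_FLOAT_FMT = "%.17g"  # round-trips IEEE doubles


def _sep(dialect: str) -> str:
    try:
        return {"tsv": "\t", "csv": ","}[dialect]
    except KeyError:
        raise ConfigError(f"unknown dialect {dialect!r}; expected 'tsv' or 'csv'") from None


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {', '.join(missing)}")


def _atomic_to_csv(df: pd.DataFrame, path, **kwargs) -> None:
    tmp = f"{path}.tmp-{os.getpid()}"
    df.to_csv(tmp, **kwargs)
    os.replace(tmp, path)


# ---------------------------------------------------------------- well tables

def read_well_table(path, dialect: str = "tsv", value_column: str = "raw_lum",
                    normalized: bool = False) -> list[ScreenPlate]:
    """Read a long-format well table into one ScreenPlate per
    (plate_id, cell_line, replicate).

    ``value_column``/``normalized`` let the same format carry normalized
    viability between pipeline stages.
    """
    df = pd.read_csv(path, sep=_sep(dialect), na_values=[NA_REP], keep_default_na=False)
    required = [c if c != "raw_lum" else value_column for c in WELL_COLUMNS]
    _require_columns(df, required, f"well table {path}")
    dup = df.duplicated(subset=["plate_id", "row", "column", "replicate"])
    if dup.any():
        first = df.loc[dup].iloc[0]
        raise IntegrityError(
            f"duplicate well coordinate (plate {first['plate_id']}, "
            f"{first['row']}{first['column']}, replicate {first['replicate']})")
    if df[value_column].isna().any():
        raise ParseError(f"well table {path}: non-numeric or missing {value_column}")
    plates = []
    for (pid, line, rep), grp in df.groupby(["plate_id", "cell_line", "replicate"],
                                            sort=True):
        wells = grp[["row", "column", "mimic_id"]].copy()
        wells["value"] = grp[value_column].astype(float).to_numpy()
        plates.append(ScreenPlate(str(pid), str(line), int(rep),
                                  wells.reset_index(drop=True),
                                  normalized=normalized))
    return plates


def write_well_table(plates: Iterable[ScreenPlate], path, dialect: str = "tsv",
                     value_column: str = "raw_lum") -> None:
    frames = []
    for p in plates:
        f = p.wells[["row", "column", "mimic_id"]].copy()
        f.insert(0, "plate_id", p.plate_id)
        f.insert(1, "cell_line", p.cell_line)
        f.insert(2, "replicate", p.replicate)
        f[value_column] = p.wells["value"].to_numpy()
        frames.append(f)
    out = pd.concat(frames, ignore_index=True)
    _atomic_to_csv(out, path, sep=_sep(dialect), index=False,
                   float_format=_FLOAT_FMT, na_rep=NA_REP)


# ------------------------------------------------------------ labeled matrices

def write_matrix(df: pd.DataFrame, path, dialect: str = "tsv",
                 index_label: str = "id") -> None:
    _atomic_to_csv(df, path, sep=_sep(dialect), index=True,
                   index_label=index_label, float_format=_FLOAT_FMT, na_rep=NA_REP)


def read_matrix(path, dialect: str = "tsv") -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep(dialect), index_col=0,
                     na_values=[NA_REP], keep_default_na=False)
    if df.index.has_duplicates:
        raise IntegrityError(f"{path}: duplicate row labels")
    for col in df.columns:
        if df[col].dtype == object:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = df.index[bad.to_numpy().nonzero()[0][0]]
                raise ParseError(f"{path}: non-numeric cell at row {row!r}, "
                                 f"column {col!r}")
            df[col] = coerced
    return df


def write_zscore_matrix(m: ZScoreMatrix, path, dialect: str = "tsv") -> None:
    write_matrix(m.z, path, dialect, index_label="mimic_id")


def read_zscore_matrix(path, dialect: str = "tsv") -> ZScoreMatrix:
    return ZScoreMatrix(read_matrix(path, dialect))


# ----------------------------------------------------------------- annotations

def write_annotations(ann: MimicAnnotations, path, dialect: str = "tsv") -> None:
    _atomic_to_csv(ann.table, path, sep=_sep(dialect), index=True,
                   index_label="mimic_id")


def read_annotations(path, dialect: str = "tsv",
                     seed_window: tuple[int, int] = (2, 8)) -> MimicAnnotations:
    df = pd.read_csv(path, sep=_sep(dialect), index_col="mimic_id",
                     na_values=[NA_REP], keep_default_na=False)
    _require_columns(df, ["mature_sequence", "seed", "family_id"], f"annotations {path}")
    return MimicAnnotations(df, seed_window)


# -------------------------------------------------------------------- survival

def read_survival(path, dialect: str = "tsv") -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep(dialect), na_values=[NA_REP],
                     keep_default_na=False)
    # accept the on-disk column name time_months as well
    df = df.rename(columns={"time_months": "time"})
    validate_survival(df)
    df["event"] = df["event"].astype(int)
    return df


def write_survival(df: pd.DataFrame, path, dialect: str = "tsv") -> None:
    validate_survival(df)
    out = df.rename(columns={"time": "time_months"})
    _atomic_to_csv(out, path, sep=_sep(dialect), index=False,
                   float_format=_FLOAT_FMT, na_rep=NA_REP)


# ----------------------------------------------------------- target predictions

def read_target_predictions(path, dialect: str = "tsv") -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep(dialect), na_values=[NA_REP],
                     keep_default_na=False)
    _require_columns(df, ["gene_id", "context_score", "is_expressed"],
                     f"target predictions {path}")
    if df["gene_id"].duplicated().any():
        raise IntegrityError(f"{path}: duplicate gene_id")
    df["is_expressed"] = df["is_expressed"].astype(bool)
    return df


def write_target_predictions(df: pd.DataFrame, path, dialect: str = "tsv") -> None:
    _atomic_to_csv(df, path, sep=_sep(dialect), index=False,
                   float_format=_FLOAT_FMT, na_rep=NA_REP)


# ------------------------------------------------------------- cluster networks

def export_cluster_network(hierarchy, path) -> None:
    """Write a ClusterHierarchy as GraphML.

    One node per base item; node attribute ``level<k>`` gives the exemplar
    label of the item's cluster at level k.  Directed edges point from each
    level's items to their exemplar at that level (exemplar self-edges
    included), tagged with a ``level`` attribute.
    """
    if not hierarchy.levels:
        raise DataError("empty cluster hierarchy")
    g = nx.DiGraph()
    base_items = hierarchy.levels[0].items
    for level_idx in range(1, len(hierarchy.levels) + 1):
        membership = hierarchy.membership(level_idx)
        for item in base_items:
            g.add_node(item)
            g.nodes[item][f"level{level_idx}"] = membership[item]
    for level_idx, res in enumerate(hierarchy.levels, start=1):
        for item, exemplar in res.assignment.items():
            g.add_edge(item, exemplar, level=level_idx)
    tmp = f"{path}.tmp-{os.getpid()}"
    nx.write_graphml(g, tmp)
    os.replace(tmp, path)


def read_cluster_network(path) -> tuple[nx.DiGraph, dict[int, dict[str, str]]]:
    """Re-import an exported network; returns the graph and per-level
    membership maps {level: {item: exemplar}}."""
    g = nx.read_graphml(path)
    memberships: dict[int, dict[str, str]] = {}
    for node, attrs in g.nodes(data=True):
        for key, val in attrs.items():
            if key.startswith("level"):
                memberships.setdefault(int(key[5:]), {})[node] = val
    return g, memberships
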