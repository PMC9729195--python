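"""Delimited-text readers/writers for connectomes, pathology and expression.

Conventions: connectome files are square tables with region labels as both
header row and first column; pathology files have region rows and
``time_<w>wk`` columns with blank cells for unquantified entries; expression
files have region rows and gene-symbol columns. Region order is resolved by
label join against the connectome, and unmatched labels are reported.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    Connectome, ExpressionTable, GeneVector, InvalidConnectomeError,
    PathologyData, Trajectory, UnknownRegionError,
)

log = logging.getLogger(__name__)

__all__ = [
    "load_connectome", "write_connectome", "load_pathology", "write_pathology",
    "load_expression", "write_expression", "write_trajectory", "write_gene",
]

_TIME_COL = re.compile(r"^time_(\d+(?:\.\d+)?)wk$")


def _read_table(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, index_col=0, sep=None, engine="python")
    except Exception as exc:
        raise ValueError(f"could not parse {path}: {exc}") from exc


def _numeric(df: pd.DataFrame, path) -> pd.DataFrame:
    out = df.apply(pd.to_numeric, errors="coerce")
    bad = out.isna() & df.notna()
    if bad.any().any():
        r = bad.any(axis=1).idxmax()
        c = bad.loc[r].idxmax()
        raise ValueError(f"non-numeric cell in {path} at row {r!r}, column {c!r}: "
                         f"{df.loc[r, c]!r}")
    return out


def load_connectome(path, hemisphere_path=None, symmetrize_check: bool = False) -> Connectome:
    """Read a square region x region weight table (CSV/TSV).

    ``hemisphere_path`` optionally names a two-column CSV (region, hemisphere)
    tagging regions left/right/none.
    """
    df = _numeric(_read_table(path), path)
    rows = [str(x) for x in df.index]
    cols = [str(x) for x in df.columns]
    if rows != cols:
        raise InvalidConnectomeError(
            f"{path}: row labels differ from column labels "
            f"(e.g. {set(rows) ^ set(cols) or 'ordering differs'})"
        )
    if df.isna().any().any():
        r = df.isna().any(axis=1).idxmax()
        raise InvalidConnectomeError(f"{path}: missing weight in row {r!r}")
    hemi: tuple[str, ...] = ()
    if hemisphere_path is not None:
        hm = pd.read_csv(hemisphere_path, index_col=0, sep=None, engine="python")
        mapping = {str(k): str(v) for k, v in hm.iloc[:, 0].items()}
        missing = [r for r in rows if r not in mapping]
        if missing:
            raise UnknownRegionError(missing, list(mapping))
        hemi = tuple(mapping[r] for r in rows)
    return Connectome(df.to_numpy(float), tuple(rows), hemi)


def write_connectome(conn: Connectome, path) -> None:
    conn.to_frame().to_csv(path)


def load_pathology(path, seed_regions, connectome: Connectome | None = None) -> PathologyData:
    """Read a region x ``time_<w>wk`` pathology table; blanks are unquantified.

    If a connectome is given, rows are label-joined into its region order;
    regions absent from the file become fully unquantified and file labels
    absent from the connectome raise an error naming them.
    """
    df = _numeric(_read_table(path), path)
    times, keep = [], []
    for c in df.columns:
        m = _TIME_COL.match(str(c))
        if not m:
            raise ValueError(f"{path}: column {c!r} does not match 'time_<weeks>wk'")
        times.append(float(m.group(1)))
        keep.append(c)
    order = np.argsort(times)
    df = df[[keep[i] for i in order]]
    times = [times[i] for i in order]
    labels = [str(x) for x in df.index]
    if connectome is not None:
        extra = sorted(set(labels) - set(connectome.region_ids))
        if extra:
            raise UnknownRegionError(extra, connectome.region_ids)
        full = pd.DataFrame(np.nan, index=list(connectome.region_ids), columns=df.columns)
        full.loc[labels] = df.to_numpy(float)
        absent = len(connectome.region_ids) - len(labels)
        if absent:
            log.info("%d connectome region(s) absent from %s: treated as unquantified",
                     absent, path)
        df, labels = full, list(connectome.region_ids)
    return PathologyData(df.to_numpy(float), np.array(times), tuple(labels),
                         tuple(seed_regions))


def write_pathology(data: PathologyData, path) -> None:
    cols = [f"time_{t:g}wk" for t in data.times]
    values = np.where(data.quantified_mask, data.values, np.nan)
    pd.DataFrame(values, index=data.region_ids, columns=cols).to_csv(path)


def load_expression(path, connectome: Connectome | None = None) -> ExpressionTable:
    """Read a region x gene expression table; missing cells get the gene median."""
    df = _numeric(_read_table(path), path)
    labels = [str(x) for x in df.index]
    if connectome is not None:
        extra = sorted(set(labels) - set(connectome.region_ids))
        if extra:
            raise UnknownRegionError(extra, connectome.region_ids)
        full = pd.DataFrame(np.nan, index=list(connectome.region_ids), columns=df.columns)
        full.loc[labels] = df.to_numpy(float)
        df, labels = full, list(connectome.region_ids)
    if df.isna().any().any():
        n = int(df.isna().sum().sum())
        log.warning("%s: imputing %d missing expression value(s) with gene medians",
                    path, n)
        df = df.fillna(df.median(axis=0))
    return ExpressionTable(df.to_numpy(float), tuple(str(c) for c in df.columns),
                           tuple(labels))


def write_expression(table: ExpressionTable, path) -> None:
    pd.DataFrame(table.values, index=table.region_ids,
                 columns=table.gene_names).to_csv(path)


def write_gene(gene: GeneVector, region_ids, path) -> None:
    pd.DataFrame({gene.name: gene.values}, index=list(region_ids)).to_csv(path)


def write_trajectory(traj: Trajectory, path) -> None:
    """Long-format (region, time_weeks, value) CSV."""
    traj.to_frame().to_csv(path, index=False)
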