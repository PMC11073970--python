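"""Readers and writers for expression matrices and clinical tables.

Expression matrices are patients-in-rows, proteins-in-columns tables of
log2-fold-change values (TSV or CSV, delimiter chosen from the file
extension).  Clinical tables are CSV with the column contract
``patient_id, os_months, os_event, crd_months, crd_event, arm`` plus
optional covariate columns; ``arm`` is restricted to VH or CC.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_ARMS = frozenset({"VH", "CC"})
CLINICAL_COLUMNS = ["os_months", "os_event", "crd_months", "crd_event", "arm"]


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def read_expression(path: str | Path) -> pd.DataFrame:
    """Parse an expression matrix; validates ids and numeric finiteness."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(_sep_for(path))[1:]
    if len(header) != len(set(header)):
        dup = next(h for h in header if header.count(h) > 1)
        raise ValueError(f"duplicate protein id: {dup!r}")
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if df.empty:
        raise ValueError(f"empty expression file: {path}")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate patient id: {dup!r}")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad][0]
            raise ValueError(f"non-numeric cell at row {row!r}, column {col!r}")
        df[col] = vals
    if np.isinf(df.to_numpy(dtype=float, na_value=np.nan)).any():
        raise ValueError("expression values must be finite")
    df.index = df.index.astype(str)
    df.index.name = "patient_id"
    return df


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep=_sep_for(path), index_label="patient_id")


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Parse a clinical table; CRD may be missing (patients never in remission)."""
    df = pd.read_csv(path, index_col="patient_id")
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate patient id: {dup!r}")
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table missing columns: {missing}")
    bad_arm = ~df["arm"].isin(VALID_ARMS)
    if bad_arm.any():
        raise ValueError(f"unknown treatment arm: {df['arm'][bad_arm].iloc[0]!r}")
    for col in ("os_months", "crd_months"):
        if (df[col].dropna() < 0).any():
            raise ValueError(f"negative time in column {col!r}")
    for col in ("os_event", "crd_event"):
        vals = df[col].dropna()
        if not vals.isin([0, 1]).all():
            raise ValueError(f"event column {col!r} must be 0/1")
    if df["os_months"].isna().any():
        raise ValueError("os_months must not be missing")
    return df


def write_clinical(clin: pd.DataFrame, path: str | Path) -> None:
    clin.to_csv(path, index_label="patient_id")


def align_cohort(
    expr: pd.DataFrame, clinical: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict both tables, in expression order, to the shared patient ids."""
    shared = expr.index.intersection(clinical.index)
    if len(shared) == 0:
        raise ValueError("no shared patient ids between expression and clinical tables")
    keep = expr.index[expr.index.isin(shared)]
    dropped = (len(expr) - len(keep)) + (len(clinical) - len(keep))
    if dropped:
        logger.info("align_cohort dropped %d non-shared patient rows", dropped)
    return expr.loc[keep], clinical.loc[keep]
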