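"""Quantile-sweep prognostic protein screen.

Every protein is split, one at a time, into quantile groups under five
schemes (median split, tertiles, quartiles, quintiles, sextiles); overall
survival is compared across the groups with a log-rank test, giving a
five-column p-value table per protein.  A protein's screen p-value is the
minimum over the five schemes, and prognostic proteins are selected at the
p < 0.05 and p < 0.01 cutoffs.  Selection uses raw (unadjusted) p-values;
BH adjustment is available in :mod:`protriage.survival` for users who want
it, and the per-scheme columns are kept so either reading is possible.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .survival import logrank_test

logger = logging.getLogger(__name__)

#: The five quantile schemes: number of groups -> column label.
QUANTILE_SCHEMES = {
    2: "p_median",
    3: "p_tertile",
    4: "p_quartile",
    5: "p_quintile",
    6: "p_sextile",
}
SCHEME_COLUMNS = list(QUANTILE_SCHEMES.values())


class DegenerateProteinError(ValueError):
    """Raised when a protein has too few distinct values to split."""


def quantile_split(values, n_groups: int) -> np.ndarray:
    """Labels 0..n_groups-1 by sample-quantile boundaries.

    Ties at a boundary all go to the lower group, so the split is
    deterministic and independent of input order.
    """
    if n_groups not in QUANTILE_SCHEMES:
        raise ValueError(f"n_groups must be one of {sorted(QUANTILE_SCHEMES)}")
    v = np.asarray(values, dtype=float)
    if np.isnan(v).any():
        raise DegenerateProteinError("degenerate protein: missing values")
    if np.unique(v).size < n_groups:
        raise DegenerateProteinError("degenerate protein: fewer distinct values than groups")
    bounds = np.quantile(v, np.arange(1, n_groups) / n_groups)
    labels = np.searchsorted(bounds, v, side="left")
    if np.unique(labels).size < n_groups:
        raise DegenerateProteinError("degenerate protein: empty quantile group")
    return labels


def screen_protein(expr_column, times, events) -> dict[str, float]:
    """Log-rank p-value under each quantile scheme, plus their minimum.

    A degenerate protein (too few distinct values for a scheme) gets NaN for
    that scheme; a protein degenerate under every scheme is effectively
    excluded (all-NaN row).
    """
    out: dict[str, float] = {}
    for g, col in QUANTILE_SCHEMES.items():
        try:
            labels = quantile_split(expr_column, g)
            out[col] = logrank_test(times, events, labels).p_value
        except DegenerateProteinError:
            out[col] = np.nan
    ps = [out[c] for c in SCHEME_COLUMNS]
    out["min_p"] = np.nan if np.all(np.isnan(ps)) else np.nanmin(ps)
    return out


def screen_proteins(expr: pd.DataFrame, clinical: pd.DataFrame) -> pd.DataFrame:
    """The full screen: one row per protein, five scheme columns, flags.

    Proteins with any missing value are excluded (all-NaN row) with a logged
    warning rather than imputed.
    """
    times = clinical["os_months"].to_numpy(dtype=float)
    events = clinical["os_event"].to_numpy(dtype=int)
    rows = {}
    n_missing = 0
    for protein in expr.columns:
        col = expr[protein].to_numpy(dtype=float)
        if np.isnan(col).any():
            n_missing += 1
            rows[protein] = {c: np.nan for c in SCHEME_COLUMNS} | {"min_p": np.nan}
            continue
        rows[protein] = screen_protein(col, times, events)
    if n_missing:
        logger.warning("excluded %d proteins with missing values from the screen", n_missing)
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "protein"
    table["excluded"] = table["min_p"].isna()
    table["prognostic_05"] = table["min_p"] < 0.05
    table["prognostic_01"] = table["min_p"] < 0.01
    return table


def select_prognostic(table: pd.DataFrame, alpha: float) -> list[str]:
    """Proteins with min_p < alpha, sorted by min_p ascending."""
    hits = table[table["min_p"] < alpha].sort_values("min_p")
    return hits.index.tolist()
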