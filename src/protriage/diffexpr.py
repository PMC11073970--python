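"""One-vs-rest differential expression and protein-protein correlation.

Differential expression per cluster uses a two-sided Wilcoxon rank-sum test
per protein, BH adjustment across proteins, and a mean-LFC effect gate:
a protein is reported when the adjusted p falls below ``alpha`` AND the
absolute difference of mean log2 expression (cluster minus rest) reaches
``lfc_threshold``.  The correlation report is pairwise Pearson r with
t-distribution p-values; pairs above ``r_threshold`` are flagged.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .survival import bh_adjust

logger = logging.getLogger(__name__)


def de_one_vs_rest(
    expr: pd.DataFrame,
    clusters: pd.Series,
    target_cluster: str,
    alpha: float = 0.05,
    lfc_threshold: float = 0.5,
    versus: str | None = None,
) -> pd.DataFrame:
    """Proteins differentially expressed in ``target_cluster``.

    By default the comparison pools every other cluster as "rest"; pass
    ``versus`` to compare against one specific cluster instead.  Returned
    rows all satisfy ``p_fdr < alpha`` and ``|effect| >= lfc_threshold``,
    with ``direction`` UP/DOWN from the sign of the effect.
    """
    clusters = clusters.loc[expr.index]
    in_target = (clusters == target_cluster).to_numpy()
    in_rest = (
        (clusters == versus).to_numpy() if versus is not None else ~in_target
    )
    if in_target.sum() < 3 or in_rest.sum() < 3:
        raise ValueError("both groups need at least 3 patients")

    X = expr.to_numpy(dtype=float)
    a, b = X[in_target], X[in_rest]
    res = stats.mannwhitneyu(a, b, alternative="two-sided", axis=0)
    effect = a.mean(axis=0) - b.mean(axis=0)
    p_fdr = bh_adjust(res.pvalue)

    table = pd.DataFrame(
        {
            "cluster": target_cluster,
            "protein": expr.columns,
            "effect": effect,
            "p_raw": res.pvalue,
            "p_fdr": p_fdr,
            "direction": np.where(effect >= 0, "UP", "DOWN"),
        }
    )
    hits = table[(table["p_fdr"] < alpha) & (table["effect"].abs() >= lfc_threshold)]
    return hits.sort_values(["p_fdr", "p_raw"]).reset_index(drop=True)


def correlate_proteins(
    expr: pd.DataFrame,
    proteins: list[str] | None = None,
    r_threshold: float = 0.60,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlation among the given proteins.

    Returns (long-format pair table, full correlation matrix).  Pairs with
    r above the threshold carry ``top_pair=True``; zero-variance proteins
    produce NaN rows with a logged warning.
    """
    sub = expr[proteins] if proteins is not None else expr
    if sub.shape[0] < 3:
        raise ValueError("need at least 3 patients")
    if sub.shape[1] < 2:
        raise ValueError("need at least 2 proteins")

    X = sub.to_numpy(dtype=float)
    sd = X.std(axis=0)
    degenerate = sd == 0
    if degenerate.any():
        logger.warning("zero-variance proteins reported as NA: %s",
                       list(sub.columns[degenerate]))
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X, rowvar=False)
    R[degenerate, :] = np.nan
    R[:, degenerate] = np.nan
    np.fill_diagonal(R, np.where(degenerate, np.nan, 1.0))

    n = X.shape[0]
    cols = sub.columns
    iu, ju = np.triu_indices(len(cols), k=1)
    r = R[iu, ju]
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
    pairs = pd.DataFrame(
        {
            "protein_a": cols[iu],
            "protein_b": cols[ju],
            "r": r,
            "p_value": p,
            "top_pair": r > r_threshold,
        }
    )
    matrix = pd.DataFrame(R, index=cols, columns=cols)
    return pairs, matrix
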