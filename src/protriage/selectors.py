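"""Sequential construction of protein selector sets and final clusters.

The pipeline peels a cohort apart in three passes.  PS1 clusters all
patients (three clusters) from the prognostic proteins of the full cohort
and classifies each cluster by its treatment-arm survival contrast: the
VH-favoring cluster becomes C1; the cluster with the weakest arm contrast
("the selector did not identify an optimal therapy") is re-clustered by PS2
into C2 and C3; the remaining cluster is re-clustered by PS3 into C4 and C5.
C5 — the PS3 cluster with the worse best-arm survival — is flagged NEITHER
when both of its arms have median OS below a threshold, yielding the
recommendation map C1 -> VH, C2/C3/C4 -> their preferred arm (CC in the
reference cohort), C5 -> NEITHER.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .progeny import ProgenyConfig, ProgenyResult, progeny_cluster
from .screen import screen_proteins, select_prognostic
from .survival import NOT_REACHED, km_fit, logrank_test, median_survival, survival_at

logger = logging.getLogger(__name__)

UNDETERMINED = "UNDETERMINED"


@dataclass
class SelectorConfig:
    cutoffs: tuple[float, ...] = (0.05,)
    top_n: tuple[int | None, ...] = (None,)
    k: int | None = None                 # forced cluster count; None = sweep
    k_candidates: tuple[int, ...] = (2, 3, 4, 5, 6)
    min_cluster_size: int = 10
    min_subcohort: int = 20
    neither_threshold: float = 15.0      # months; both arms below => NEITHER
    poor_threshold: float = 20.0         # months; annotation for poor clusters
    n_iterations: int = 50
    m_per_cluster: int = 20
    seed: int = 0


@dataclass
class ArmContrast:
    """Per-arm outcome summary of one cluster and the verdict it implies."""

    per_arm: dict[str, dict[str, float]]
    preferred_arm: str            # VH | CC | NEITHER | UNDETERMINED
    margin: float
    best_median: float
    both_poor: bool


@dataclass
class SelectorSet:
    name: str
    proteins: list[str]
    cohort_ids: pd.Index
    clustering: ProgenyResult
    outcome_summary: pd.DataFrame = field(repr=False)
    os_logrank_p: float = np.nan
    crd_logrank_p: float = np.nan


@dataclass
class FinalClustering:
    labels: pd.Series
    provenance: dict[str, str]
    recommendation: dict[str, str]


def zscore(expr: pd.DataFrame) -> pd.DataFrame:
    """Per-protein z-score within the fitted cohort; zero-variance guarded."""
    sd = expr.std(axis=0, ddof=0).replace(0.0, 1.0)
    return (expr - expr.mean(axis=0)) / sd


def _cluster_outcomes(clinical: pd.DataFrame, labels: np.ndarray) -> pd.DataFrame:
    rows = []
    for cl in np.unique(labels):
        sub = clinical[labels == cl]
        for arm in ("VH", "CC"):
            a = sub[sub["arm"] == arm]
            if len(a) == 0:
                rows.append({"cluster": int(cl), "arm": arm, "n": 0,
                             "median_os": np.nan, "s60": np.nan, "median_crd": np.nan})
                continue
            curve = km_fit(a["os_months"], a["os_event"])
            crd = a.dropna(subset=["crd_months"])
            med_crd = (
                median_survival(km_fit(crd["crd_months"], crd["crd_event"]))
                if len(crd) else np.nan
            )
            rows.append({
                "cluster": int(cl), "arm": arm, "n": len(a),
                "median_os": median_survival(curve),
                "s60": survival_at(curve, 60.0),
                "median_crd": med_crd,
            })
    return pd.DataFrame(rows)


def _separation_p(clinical: pd.DataFrame, labels: np.ndarray,
                  time_col: str, event_col: str) -> float:
    """Treatment-discrimination score of a clustering for one endpoint.

    Within each cluster, VH and CC survival are compared by log-rank; the
    per-cluster p-values are Fisher-combined.  This scores what the selector
    exists to find — clusters whose KM curves split by treatment arm — and,
    unlike an arm-pooled log-rank across clusters, it does not reward
    partitions that merely stratify marginal survival.
    """
    from scipy import stats as _stats

    notna = clinical[time_col].notna().to_numpy()
    sub = clinical[notna]
    lab = labels[notna]
    chi2, k = 0.0, 0
    for c in np.unique(lab):
        m = lab == c
        if np.unique(sub["arm"][m]).size < 2 or m.sum() < 4:
            continue
        p = logrank_test(sub[time_col][m], sub[event_col][m], sub["arm"][m]).p_value
        chi2 += -2.0 * np.log(max(p, 1e-300))
        k += 1
    if k == 0:
        return np.nan
    return float(_stats.chi2.sf(chi2, 2 * k))


def build_selector(
    expr: pd.DataFrame,
    clinical: pd.DataFrame,
    config: SelectorConfig,
    name: str = "PS",
) -> SelectorSet:
    """Screen the (sub)cohort and pick the best-separating protein set.

    Candidate protein sets cross the two screen cutoffs with the configured
    top-N truncations; each candidate's standardized submatrix is progeny-
    clustered and candidates are ranked by the OS log-rank p across the
    resulting clusters, with the CRD log-rank p as the tie-break.
    """
    table = screen_proteins(expr, clinical)
    candidates: list[list[str]] = []
    for cutoff in config.cutoffs:
        for n in config.top_n:
            proteins = select_prognostic(table, cutoff)
            if n is not None:
                proteins = proteins[:n]
            if len(proteins) >= 2 and proteins not in candidates:
                candidates.append(proteins)
    if not candidates:
        raise ValueError(f"{name}: no candidate protein set passed the screen")

    k_candidates = [config.k] if config.k is not None else list(config.k_candidates)
    pconfig = ProgenyConfig(config.n_iterations, config.m_per_cluster, seed=config.seed)

    best = None
    for proteins in candidates:
        Z = zscore(expr[proteins]).to_numpy()
        result = progeny_cluster(Z, k_candidates, pconfig)
        sizes = np.bincount(result.assignments)
        if (sizes >= config.min_cluster_size).sum() < 2:
            continue
        os_p = _separation_p(clinical, result.assignments, "os_months", "os_event")
        crd_p = _separation_p(clinical, result.assignments, "crd_months", "crd_event")
        key = (os_p if np.isfinite(os_p) else 1.0, crd_p if np.isfinite(crd_p) else 1.0)
        if best is None or key < best[0]:
            best = (key, proteins, result, os_p, crd_p)
    if best is None:
        raise ValueError(
            f"{name}: no candidate produced >=2 clusters with "
            f">={config.min_cluster_size} patients"
        )
    _, proteins, result, os_p, crd_p = best
    return SelectorSet(
        name=name,
        proteins=proteins,
        cohort_ids=expr.index,
        clustering=result,
        outcome_summary=_cluster_outcomes(clinical, result.assignments),
        os_logrank_p=os_p,
        crd_logrank_p=crd_p,
    )


def arm_contrast(clinical: pd.DataFrame, neither_threshold: float = 12.0) -> ArmContrast:
    """KM summaries per arm and the therapy verdict for one patient cluster.

    The preferred arm is the one with the larger median OS (a median the
    curve never reaches beats any finite median); NEITHER when both arms'
    medians fall below the threshold; UNDETERMINED when an arm is absent or
    the medians tie.  The recorded margin is the absolute difference in
    five-year survival between the arms, which stays finite when a median
    is never reached.
    """
    if len(clinical) == 0:
        raise ValueError("empty cluster")
    per_arm: dict[str, dict[str, float]] = {}
    for arm in ("VH", "CC"):
        sub = clinical[clinical["arm"] == arm]
        if len(sub) == 0:
            continue
        curve = km_fit(sub["os_months"], sub["os_event"])
        per_arm[arm] = {
            "n": len(sub),
            "median_os": median_survival(curve),
            "s60": survival_at(curve, 60.0),
        }
    if len(per_arm) < 2:
        logger.info("arm contrast undetermined: only %s present", list(per_arm))
        only = next(iter(per_arm.values()), {"median_os": np.nan})
        return ArmContrast(per_arm, UNDETERMINED, 0.0, only["median_os"], False)

    m_vh, m_cc = per_arm["VH"]["median_os"], per_arm["CC"]["median_os"]
    both_poor = m_vh < neither_threshold and m_cc < neither_threshold
    # bounded contrast measure: difference in five-year survival, robust to
    # medians the follow-up never reaches
    margin = abs(per_arm["VH"]["s60"] - per_arm["CC"]["s60"])
    best = max(m_vh, m_cc)
    if m_vh == m_cc:
        preferred = UNDETERMINED
    elif both_poor:
        preferred = "NEITHER"
    elif m_vh > m_cc:
        preferred = "VH"
    elif m_cc > m_vh:
        preferred = "CC"
    else:
        preferred = UNDETERMINED
    return ArmContrast(per_arm, preferred, margin, best, both_poor)


def filter_treatment_purity(clinical: pd.DataFrame) -> pd.DataFrame:
    """Sharpen the arm contrast when regimen detail flags are available.

    Drops VH patients who also received cytarabine on top of the
    HMA+venetoclax backbone, and restricts CC to cytarabine-treated
    patients.  A no-op when the flag columns are absent.
    """
    cols = {"received_hma_ven", "received_arac"}
    if not cols.issubset(clinical.columns):
        return clinical
    vh_drop = (
        (clinical["arm"] == "VH")
        & clinical["received_hma_ven"].astype(bool)
        & clinical["received_arac"].astype(bool)
    )
    cc_drop = (clinical["arm"] == "CC") & ~clinical["received_arac"].astype(bool)
    kept = clinical[~(vh_drop | cc_drop)]
    logger.info("treatment-purity filter removed %d patients", len(clinical) - len(kept))
    return kept


def _prefers_vh(contrast: ArmContrast) -> bool:
    return contrast.preferred_arm == "VH"


def run_sequential(
    expr: pd.DataFrame,
    clinical: pd.DataFrame,
    config: SelectorConfig | None = None,
) -> tuple[FinalClustering, dict[str, SelectorSet]]:
    """PS1 on everyone, PS2 on the indeterminate cluster, PS3 on the poor one.

    Returns the merged five-way clustering with per-label provenance and the
    therapy recommendation map, plus the three fitted selector sets.
    """
    config = config or SelectorConfig()
    if clinical["arm"].nunique() < 2:
        raise ValueError("run_sequential needs both treatment arms")

    ps1_cfg = replace(config, k=3 if config.k is None else config.k)
    ps1 = build_selector(expr, clinical, ps1_cfg, name="PS1")
    labels1 = ps1.clustering.assignments

    contrasts = {
        int(c): arm_contrast(clinical[labels1 == c], config.neither_threshold)
        for c in np.unique(labels1)
    }
    vh_clusters = [c for c, ct in contrasts.items() if _prefers_vh(ct)]
    c1_cluster = max(vh_clusters, key=lambda c: contrasts[c].margin) if vh_clusters else None
    remaining = [c for c in contrasts if c != c1_cluster]
    if c1_cluster is None:
        logger.info("no PS1 cluster favors VH; pipeline emits zero VH recommendations")
        ps3_feed = [min(remaining, key=lambda c: contrasts[c].best_median)]
        ps2_feed = [c for c in remaining if c not in ps3_feed]
    else:
        # weakest arm contrast = the cluster PS1 could not triage -> PS2;
        # the rest (poor or strongly CC-favoring) -> PS3
        ps2_feed = [min(remaining, key=lambda c: contrasts[c].margin)]
        ps3_feed = [c for c in remaining if c not in ps2_feed]

    clinical_f = filter_treatment_purity(clinical)

    labels = pd.Series(index=expr.index, dtype=object, name="cluster")
    provenance: dict[str, str] = {}
    recommendation: dict[str, str] = {}

    if c1_cluster is not None:
        mask = pd.Series(labels1 == c1_cluster, index=expr.index)
        labels[mask] = "C1"
        provenance["C1"] = "PS1"
        recommendation["C1"] = "VH"

    def _subcohort(feed: list[int], stage: str):
        mask = pd.Series(np.isin(labels1, feed), index=expr.index)
        ids = expr.index[mask & expr.index.isin(clinical_f.index)]
        if len(ids) < config.min_subcohort:
            raise ValueError(f"{stage}: subcohort too small ({len(ids)} patients)")
        return expr.loc[ids], clinical_f.loc[ids]

    def _stage_pair(stage_name: str, feed: list[int], label_pair: tuple[str, str],
                    seed_offset: int):
        sub_expr, sub_clin = _subcohort(feed, stage_name)
        cfg = replace(config, k=2, seed=config.seed + seed_offset)
        ps = build_selector(sub_expr, sub_clin, cfg, name=stage_name)
        assign = ps.clustering.assignments
        pair_contrasts = {
            int(c): arm_contrast(sub_clin[assign == c], config.neither_threshold)
            for c in np.unique(assign)
        }
        # better best-arm survival takes the first label of the pair
        order = sorted(pair_contrasts, key=lambda c: -_rank_median(pair_contrasts[c]))
        for lbl, c in zip(label_pair, order):
            ids = sub_expr.index[assign == c]
            labels[ids] = lbl
            provenance[lbl] = stage_name
        return {lbl: pair_contrasts[c] for lbl, c in zip(label_pair, order)}, ps

    def _rank_median(ct: ArmContrast) -> float:
        return 1e9 if ct.best_median == NOT_REACHED else ct.best_median

    def _arm_recommendation(ct: ArmContrast) -> str:
        if ct.preferred_arm in ("VH", "CC"):
            return ct.preferred_arm
        if ct.preferred_arm == "NEITHER":
            # outside PS3 the verdict falls back to the better arm
            return "VH" if ct.per_arm.get("VH", {}).get("median_os", 0) > \
                ct.per_arm.get("CC", {}).get("median_os", 0) else "CC"
        arms = list(ct.per_arm)
        return arms[0] if len(arms) == 1 else "CC"

    selector_sets = {"PS1": ps1}
    if ps2_feed:
        pair, ps2 = _stage_pair("PS2", ps2_feed, ("C2", "C3"), seed_offset=1)
        selector_sets["PS2"] = ps2
        for lbl, ct in pair.items():
            recommendation[lbl] = _arm_recommendation(ct)
    if ps3_feed:
        pair, ps3 = _stage_pair("PS3", ps3_feed, ("C4", "C5"), seed_offset=2)
        selector_sets["PS3"] = ps3
        recommendation["C4"] = _arm_recommendation(pair["C4"])
        recommendation["C5"] = (
            "NEITHER" if pair["C5"].both_poor else _arm_recommendation(pair["C5"])
        )

    unlabeled = labels.isna()
    if unlabeled.any():
        # patients removed by the treatment-purity filter keep their PS1 pool
        pool_label = {c: ("C2" if c in ps2_feed else "C5") for c in remaining}
        for c, lbl in pool_label.items():
            mask = pd.Series(labels1 == c, index=expr.index) & unlabeled
            labels[mask] = lbl
    final = FinalClustering(labels=labels, provenance=provenance,
                            recommendation=recommendation)
    return final, selector_sets
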