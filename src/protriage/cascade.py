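"""Three-stage random-forest cascade mapping protein profiles to therapy.

The Protein Classifier distinguishes, sequentially: (1) the VH-responsive
cluster C1 from everyone else; (2) the good-prognosis CC clusters {C2, C4}
from {C3, C5}; (3) C3 (CC plus intensification) from C5 (neither therapy).
Each stage is a random forest tuned by holdout grid search, pruned to at
most six proteins by exhaustively refitting every nonempty subset of the
six top Shapley-ranked features, and scored by the concordance index
``(#concordant + 0.5 * #ties) / #permissible`` over positive-negative pairs.

At inference time every patient routes through stage 1 first: a stage-1
positive is recommended VH; otherwise a stage-2 positive is recommended CC;
otherwise stage 3 decides CC_INTENSIFY (C3-like) vs NEITHER (C5-like).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from .shapley import tree_shap_values

logger = logging.getLogger(__name__)

VH, CC, CC_INTENSIFY, NEITHER = "VH", "CC", "CC_INTENSIFY", "NEITHER"

#: Therapy implied by a true cluster label.
LABEL_THERAPY = {"C1": VH, "C2": CC, "C3": CC_INTENSIFY, "C4": CC, "C5": NEITHER}

#: Stage definitions: (eligible clusters, positive clusters).
STAGE_DEFS = {
    1: (("C1", "C2", "C3", "C4", "C5"), ("C1",)),
    2: (("C2", "C3", "C4", "C5"), ("C2", "C4")),
    3: (("C3", "C5"), ("C3",)),
}


def default_grid() -> dict[str, list]:
    """The 150-combination hyperparameter grid (10 x 5 x 3)."""
    return {
        "n_estimators": [25, 50, 75, 100, 150, 200, 300, 400, 500, 750],
        "max_depth": [2, 3, 4, 6, 8],
        "min_samples_leaf": [1, 3, 5],
    }


def expand_grid(grid: dict[str, list]) -> list[dict]:
    keys = ["n_estimators", "max_depth", "min_samples_leaf"]
    if not all(grid.get(k) for k in keys):
        raise ValueError("empty hyperparameter grid")
    return [dict(zip(keys, combo)) for combo in itertools.product(*(grid[k] for k in keys))]


@dataclass
class SplitSpec:
    dev_fraction: float = 0.8
    train_fraction_of_dev: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.dev_fraction < 1 and 0 < self.train_fraction_of_dev < 1):
            raise ValueError("split fractions must lie in (0, 1)")


@dataclass
class StageModel:
    stage: int
    positive_clusters: tuple[str, ...]
    hyperparameters: dict
    selected_proteins: list[str]
    validation_c_index: float
    test_c_index: float
    model: RandomForestClassifier = field(repr=False)
    shap_ranking: pd.Series = field(repr=False, default=None)


@dataclass
class CascadeModel:
    stages: dict[int, StageModel]
    threshold: float = 0.5


def split_data(labels, spec: SplitSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stratified train/validation/test index split (default 60/20/20).

    Re-draws with incremented seeds up to 20 times if any class is missing
    from any partition.
    """
    y = np.asarray(labels)
    n = y.size
    if n < 10:
        raise ValueError("need at least 10 patients to split")
    idx = np.arange(n)
    classes = np.unique(y)
    for attempt in range(20):
        seed = spec.seed + attempt
        dev, test = train_test_split(
            idx, train_size=spec.dev_fraction, random_state=seed, stratify=y
        )
        train, val = train_test_split(
            dev, train_size=spec.train_fraction_of_dev, random_state=seed,
            stratify=y[dev],
        )
        parts = (train, val, test)
        if all(np.isin(classes, y[p]).all() for p in parts):
            return parts
    raise ValueError("could not produce a split containing every class in every partition")


def c_index(scores, binary_labels) -> float:
    """Concordance over positive-negative pairs; ties count half."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(binary_labels)
    pos, neg = s[y == 1], s[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("c_index needs both classes")
    diff = pos[:, None] - neg[None, :]
    concordant = (diff > 0).sum()
    ties = (diff == 0).sum()
    return float((concordant + 0.5 * ties) / diff.size)


def _fit_forest(X, y, params: dict, seed: int) -> RandomForestClassifier:
    model = RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    model.fit(X, y)
    return model


def grid_search(X_train, y_train, X_val, y_val, grid: dict[str, list], seed: int) -> dict:
    """Holdout grid search scored by validation C-index.

    Ties resolve to the smallest forest (fewest trees, then shallowest, then
    largest leaves).
    """
    combos = expand_grid(grid)
    best, best_score = None, -np.inf
    for params in combos:
        model = _fit_forest(X_train, y_train, params, seed)
        score = c_index(model.predict_proba(X_val)[:, 1], y_val)
        key = (score, -params["n_estimators"], -params["max_depth"], params["min_samples_leaf"])
        if best is None or key > best_key:
            best, best_key, best_score = params, key, score
    logger.info("grid search evaluated %d combinations; best %s (val C-index %.3f)",
                len(combos), best, best_score)
    return best


def shap_rank(model, X, feature_names) -> pd.Series:
    """Features ordered by mean |Shapley attribution| over the given samples."""
    phi, _ = tree_shap_values(model, np.asarray(X, dtype=float))
    importance = np.abs(phi).mean(axis=0)
    return pd.Series(importance, index=list(feature_names)).sort_values(
        ascending=False, kind="stable"
    )


def select_subset(
    X_train, y_train, X_val, y_val, X_test, y_test,
    ranked_proteins: list[str], columns: list[str], params: dict, seed: int,
    stage: int, positive_clusters: tuple[str, ...],
) -> StageModel:
    """Exhaustive search over the 63 nonempty subsets of the top 6 proteins.

    Each subset is refit with the grid-searched hyperparameters and scored
    on the validation set; ties prefer the smaller subset, then the one
    whose members rank earlier.
    """
    top = ranked_proteins[:6]
    col_idx = {c: i for i, c in enumerate(columns)}
    best = None
    n_eval = 0
    for size in range(1, len(top) + 1):
        for combo in itertools.combinations(range(len(top)), size):
            subset = [top[i] for i in combo]
            cols = [col_idx[p] for p in subset]
            model = _fit_forest(X_train[:, cols], y_train, params, seed)
            score = c_index(model.predict_proba(X_val[:, cols])[:, 1], y_val)
            n_eval += 1
            key = (score, -size, tuple(-i for i in combo))
            if best is None or key > best[0]:
                best = (key, subset, cols, model)
    logger.info("stage %d subset search: %d subsets evaluated", stage, n_eval)
    _, subset, cols, model = best
    val_ci = best[0][0]
    test_ci = c_index(model.predict_proba(X_test[:, cols])[:, 1], y_test)
    return StageModel(
        stage=stage,
        positive_clusters=positive_clusters,
        hyperparameters=params,
        selected_proteins=subset,
        validation_c_index=float(val_ci),
        test_c_index=float(test_ci),
        model=model,
    )


def train_cascade(
    expr: pd.DataFrame,
    cluster_labels: pd.Series,
    spec: SplitSpec | None = None,
    grid: dict[str, list] | None = None,
) -> tuple[CascadeModel, dict[int, dict[str, np.ndarray]]]:
    """Fit the three stage models on their sub-cohorts.

    Returns the cascade plus, per stage, the patient-id partitions used
    (train/validation/test), so evaluation can be restricted to held-out
    patients.
    """
    spec = spec or SplitSpec()
    grid = grid or default_grid()
    columns = expr.columns.tolist()
    stages: dict[int, StageModel] = {}
    splits: dict[int, dict[str, np.ndarray]] = {}
    for stage, (eligible, positive) in STAGE_DEFS.items():
        mask = cluster_labels.isin(eligible).to_numpy()
        X = expr.to_numpy(dtype=float)[mask]
        y = cluster_labels[mask].isin(positive).to_numpy().astype(int)
        ids = expr.index[mask]
        tr, va, te = split_data(y, SplitSpec(spec.dev_fraction, spec.train_fraction_of_dev,
                                             spec.seed + stage))
        params = grid_search(X[tr], y[tr], X[va], y[va], grid, seed=spec.seed + stage)
        full_model = _fit_forest(X[tr], y[tr], params, seed=spec.seed + stage)
        dev = np.concatenate([tr, va])
        ranking = shap_rank(full_model, X[dev], columns)
        stage_model = select_subset(
            X[tr], y[tr], X[va], y[va], X[te], y[te],
            ranking.index.tolist(), columns, params, spec.seed + stage,
            stage, positive,
        )
        stage_model.shap_ranking = ranking
        stages[stage] = stage_model
        splits[stage] = {"train": ids[tr].to_numpy(), "validation": ids[va].to_numpy(),
                         "test": ids[te].to_numpy()}
    return CascadeModel(stages=stages), splits


def _stage_scores(stage: StageModel, expr: pd.DataFrame) -> np.ndarray:
    missing = [p for p in stage.selected_proteins if p not in expr.columns]
    if missing:
        raise KeyError(f"missing protein in expression input: {missing[0]!r}")
    X = expr[stage.selected_proteins].to_numpy(dtype=float)
    return stage.model.predict_proba(X)[:, 1]


def cascade_predict(expr: pd.DataFrame, cascade: CascadeModel) -> pd.DataFrame:
    """Route patients through the cascade; returns recommendation + scores.

    Stage-1 positives get VH regardless of the later stages; stage-2
    positives get CC; stage 3 splits the rest into CC_INTENSIFY vs NEITHER.
    """
    scores = {s: _stage_scores(m, expr) for s, m in cascade.stages.items()}
    thr = cascade.threshold
    rec = np.where(
        scores[1] >= thr, VH,
        np.where(scores[2] >= thr, CC, np.where(scores[3] >= thr, CC_INTENSIFY, NEITHER)),
    )
    return pd.DataFrame(
        {
            "recommendation": rec,
            "stage1_score": scores[1],
            "stage2_score": scores[2],
            "stage3_score": scores[3],
        },
        index=expr.index,
    )


def evaluate_cascade(
    expr: pd.DataFrame, true_clusters: pd.Series, cascade: CascadeModel
) -> dict:
    """Cascade metrics on labelled patients.

    Reports the correct-therapy fraction (CC and CC_INTENSIFY both count as
    CC-based therapy), the VH<->CC misassignment fraction, the fraction of
    true-C5 patients assigned any therapy, stage-wise sensitivity and
    specificity, pooled (micro-averaged) accuracy, and the confusion table
    of recommendation vs label-implied therapy.
    """
    if true_clusters.isna().any():
        raise ValueError("missing cluster labels")
    preds = cascade_predict(expr, cascade)
    implied = true_clusters.map(LABEL_THERAPY)
    if implied.isna().any():
        raise ValueError(f"unknown cluster label: {true_clusters[implied.isna()].iloc[0]!r}")

    def arm(t):
        return CC if t == CC_INTENSIFY else t

    rec_arm = preds["recommendation"].map(arm)
    implied_arm = implied.map(arm)
    correct = float((rec_arm == implied_arm).mean())
    crossed = float((
        ((rec_arm == VH) & (implied_arm == CC)) | ((rec_arm == CC) & (implied_arm == VH))
    ).mean())
    c5_mask = true_clusters == "C5"
    c5_assigned = (
        float((preds.loc[c5_mask, "recommendation"] != NEITHER).mean())
        if c5_mask.any() else np.nan
    )

    stage_metrics = {}
    pooled_tp = pooled_tn = pooled_n = 0
    for stage, (eligible, positive) in STAGE_DEFS.items():
        mask = true_clusters.isin(eligible).to_numpy()
        if not mask.any():
            continue
        y = true_clusters[mask].isin(positive).to_numpy().astype(int)
        score = preds[f"stage{stage}_score"].to_numpy()[mask]
        pred = (score >= cascade.threshold).astype(int)
        tp = int(((pred == 1) & (y == 1)).sum())
        tn = int(((pred == 0) & (y == 0)).sum())
        sens = tp / max((y == 1).sum(), 1)
        spec = tn / max((y == 0).sum(), 1)
        stage_metrics[stage] = {
            "sensitivity": float(sens),
            "specificity": float(spec),
            "c_index": c_index(score, y) if 0 < y.sum() < y.size else np.nan,
            "n": int(mask.sum()),
        }
        pooled_tp += tp
        pooled_tn += tn
        pooled_n += int(mask.sum())

    confusion = pd.crosstab(implied, preds["recommendation"],
                            rownames=["implied"], colnames=["recommended"])
    return {
        "correct_therapy_fraction": correct,
        "misassigned_fraction": crossed,
        "c5_assigned_fraction": c5_assigned,
        "stage_metrics": stage_metrics,
        "pooled_accuracy": (pooled_tp + pooled_tn) / pooled_n if pooled_n else np.nan,
        "confusion": confusion,
    }
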