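"""Synthetic RPPA cohort generator with planted cluster and survival structure.

Emulates a newly-diagnosed AML cohort profiled by reverse-phase protein
arrays: five latent protein-signature clusters, two treatment arms
(venetoclax + hypomethylating agent, ``VH``, vs conventional chemotherapy,
``CC``), and cluster-by-arm exponential survival with configurable medians.
Expression values are log2 fold-changes (LFC) versus a normal-bone-marrow
CD34+ reference, modelled as a cluster signature plus Gaussian noise.

The planted signatures are built from a handful of between-cluster contrast
axes chosen so that (a) the five clusters embed with C2/C3 and C4/C5 as the
closest pairs — a coarse k=3 clustering merges those pairs, and a k=2
clustering within each pooled pair recovers the individual clusters, the
nested structure the sequential selector pipeline peels apart — and (b)
every axis opposes clusters with clearly different survival, so that a
marginal survival screen reliably retains markers for every cluster
boundary.  Constraint (b) is what real prognostic proteins satisfy by
construction (they were screened on survival), and it is not free: with the
survival table of the reference cohort, a pure C1-vs-rest or
{C2,C3}-vs-{C4,C5} indicator protein is only weakly prognostic, because
each side mixes long- and short-lived patients into similar marginal
curves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CLUSTERS = ("C1", "C2", "C3", "C4", "C5")
ARMS = ("VH", "CC")

#: Cluster sizes of the motivating 419-patient cohort: 91/69/113/85/61.
DEFAULT_CLUSTER_PROPS = (91 / 419, 69 / 419, 113 / 419, 85 / 419, 61 / 419)

#: Cluster-by-arm median overall survival in months, rows C1..C5, columns
#: (VH, CC).  "Median not reached within follow-up" arms are encoded as a
#: finite large median (200 mo) so the exponential rate stays well defined.
DEFAULT_MEDIAN_OS = (
    (68.5, 19.4),
    (12.7, 200.0),
    (6.4, 12.2),
    (10.4, 200.0),
    (2.9, 8.6),
)

#: Super-groups that make the planted structure nested: PS1-level clustering
#: should merge C2+C3 and C4+C5.
SUPER_GROUPS = ((0,), (1, 2), (3, 4))

#: Default signature architecture: disjoint marker blocks, each an axis of
#: between-cluster contrast.  Each entry maps a block name to (per-cluster
#: coefficients C1..C5, fraction of the marker budget).  Within a block,
#: half the proteins carry the pattern up and half down; a cluster's
#: signature is coefficient x signature_effect.  Every axis opposes a
#: long-lived cluster (C2 or C4) or a distinct-survival level set, keeping
#: each block marginally prognostic; jointly the axes embed the clusters
#: with C2/C3 and C4/C5 as the closest pairs and C1 well separated.
DEFAULT_SIGNATURE_PATTERNS: dict[str, tuple[tuple[float, ...], float]] = {
    "c1_axis": ((-2.0, 0.0, 1.0, 0.0, 1.0), 0.22),
    "c2_axis": ((-1.0, 2.0, 0.0, -1.0, -1.0), 0.18),
    "c4_axis": ((-1.0, -1.0, 0.0, 2.0, 0.0), 0.18),
    "c3_axis": ((0.0, 0.0, 2.0, -1.0, 0.0), 0.14),
    "c5_axis": ((0.0, 0.0, 1.0, 0.0, -2.0), 0.14),
    "c2_vs_c4_axis": ((0.0, 1.0, 0.0, -1.0, 0.0), 0.14),
}


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort.

    ``signature_effect`` is the LFC scale (log2 units) multiplying the
    contrast-axis coefficients; ``noise_sd`` the within-cluster LFC standard
    deviation; ``frac_marker_proteins`` the fraction of proteins carrying
    any cluster signal.  ``signature_patterns`` (name -> (five per-cluster
    coefficients, budget fraction)) defaults to the six-axis architecture
    and can be overridden to plant any alternative structure, e.g. three
    collapsed signatures.
    """

    n_patients: int = 419
    n_proteins: int = 411
    cluster_props: tuple[float, ...] = DEFAULT_CLUSTER_PROPS
    signature_effect: float = 2.0
    frac_marker_proteins: float = 0.25
    noise_sd: float = 1.0
    signature_patterns: dict[str, tuple[tuple[float, ...], float]] | None = None
    arm_prob_vh: float = 79 / 419
    median_os_months: tuple[tuple[float, float], ...] = DEFAULT_MEDIAN_OS
    median_crd_months: tuple[tuple[float, float], ...] | None = None
    remission_prob: float = 274 / 419
    censor_horizon_months: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.cluster_props) != 5:
            raise ValueError("cluster_props must have 5 entries")
        if not np.isclose(sum(self.cluster_props), 1.0):
            raise ValueError("cluster_props must sum to 1")
        if not 0.0 <= self.arm_prob_vh <= 1.0:
            raise ValueError("arm_prob_vh must be in [0, 1]")
        if not 0.0 < self.frac_marker_proteins <= 1.0:
            raise ValueError("frac_marker_proteins must be in (0, 1]")
        if self.signature_patterns is None:
            self.signature_patterns = dict(DEFAULT_SIGNATURE_PATTERNS)
        for name, (coeffs, frac) in self.signature_patterns.items():
            if len(coeffs) != 5:
                raise ValueError(f"pattern {name!r} needs 5 coefficients")
            if frac <= 0:
                raise ValueError(f"pattern {name!r} needs a positive budget fraction")
        if not np.isclose(sum(f for _, f in self.signature_patterns.values()), 1.0):
            raise ValueError("signature pattern budget fractions must sum to 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.median_crd_months is None:
            self.median_crd_months = tuple(
                tuple(0.7 * m for m in row) for row in self.median_os_months
            )
        for table in (self.median_os_months, self.median_crd_months):
            arr = np.asarray(table, dtype=float)
            if arr.shape != (5, 2):
                raise ValueError("median tables must be 5x2 (clusters x arms)")
            if not (arr > 0).all():
                raise ValueError("all medians must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticCohort:
    """Expression matrix, clinical table and ground-truth labels for one draw."""

    expression: pd.DataFrame
    clinical: pd.DataFrame
    true_cluster: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if not (
            self.expression.index.equals(self.clinical.index)
            and self.expression.index.equals(self.true_cluster.index)
        ):
            raise ValueError("expression, clinical and true_cluster must share one patient index")


def marker_blocks(config: GeneratorConfig) -> dict[str, np.ndarray]:
    """Protein indices of the disjoint contrast blocks.

    The marker budget ``round(frac_marker_proteins * n_proteins)`` is
    divided among the configured patterns by their budget fractions (the
    last block absorbs the rounding remainder).
    """
    total = round(config.frac_marker_proteins * config.n_proteins)
    names = list(config.signature_patterns)
    sizes = {name: int(config.signature_patterns[name][1] * total) for name in names}
    sizes[names[-1]] += total - sum(sizes.values())
    if min(sizes.values()) < 1:
        raise ValueError("too few proteins: a marker block would be empty")
    blocks: dict[str, np.ndarray] = {}
    start = 0
    for name in names:
        blocks[name] = np.arange(start, start + sizes[name])
        start += sizes[name]
    return blocks


def make_signatures(config: GeneratorConfig) -> np.ndarray:
    """Per-cluster protein-effect vectors, shape (5, n_proteins).

    Within each contrast block half the proteins go up and half down (the
    heatmap's up- and down-regulated marker arms); a cluster's signature on
    a block is its pattern coefficient times ``signature_effect`` times the
    block's up/down pattern.  Proteins outside every block are zero in
    every signature.
    """
    blocks = marker_blocks(config)
    sig = np.zeros((5, config.n_proteins))
    for name, idx in blocks.items():
        coeffs, _ = config.signature_patterns[name]
        m = idx.size
        pattern = np.where(
            np.arange(m) < m // 2 + m % 2, config.signature_effect,
            -config.signature_effect,
        )
        for c, coef in enumerate(coeffs):
            sig[c, idx] = coef * pattern
    return sig


def _draw_survival(
    rng: np.random.Generator,
    medians: np.ndarray,
    cluster: np.ndarray,
    arm_is_vh: np.ndarray,
    horizon: float,
) -> tuple[np.ndarray, np.ndarray]:
    rate = np.log(2) / medians[cluster, np.where(arm_is_vh, 0, 1)]
    draw = rng.exponential(1.0 / rate)
    times = np.minimum(draw, horizon)
    events = (draw <= horizon).astype(int)
    return times, events


def simulate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Draw one cohort: expression, clinical outcomes and true labels.

    Expression is signature + N(0, noise_sd) per entry; the treatment arm is
    Bernoulli(arm_prob_vh); overall-survival time is exponential with the
    configured cluster-by-arm median, administratively censored at the
    horizon.  Complete-remission duration is drawn the same way for the
    fraction of patients who achieve remission and is missing otherwise.
    Identical (config, seed) gives a bit-identical cohort.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    props = np.asarray(config.cluster_props)
    expected = n * props
    if (expected < 10).any():
        logger.warning(
            "expected cluster sizes below 10 patients: %s",
            np.round(expected, 1).tolist(),
        )

    cluster = rng.choice(5, size=n, p=props)
    sig = make_signatures(config)
    expr = sig[cluster] + rng.normal(0.0, config.noise_sd, size=(n, config.n_proteins))

    arm_is_vh = rng.random(n) < config.arm_prob_vh
    os_t, os_e = _draw_survival(
        rng, np.asarray(config.median_os_months), cluster, arm_is_vh,
        config.censor_horizon_months,
    )
    crd_t, crd_e = _draw_survival(
        rng, np.asarray(config.median_crd_months), cluster, arm_is_vh,
        config.censor_horizon_months,
    )
    in_remission = rng.random(n) < config.remission_prob
    crd_t = np.where(in_remission, crd_t, np.nan)
    crd_e = np.where(in_remission, crd_e, np.nan)

    width = len(str(n))
    patients = pd.Index([f"P{i + 1:0{width}d}" for i in range(n)], name="patient_id")
    proteins = [f"PR{j + 1:04d}" for j in range(config.n_proteins)]

    expression = pd.DataFrame(expr, index=patients, columns=proteins)
    clinical = pd.DataFrame(
        {
            "os_months": os_t,
            "os_event": os_e,
            "crd_months": crd_t,
            "crd_event": crd_e,
            "arm": np.where(arm_is_vh, "VH", "CC"),
        },
        index=patients,
    )
    true_cluster = pd.Series(
        [CLUSTERS[c] for c in cluster], index=patients, name="true_cluster"
    )
    return SyntheticCohort(expression, clinical, true_cluster)
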