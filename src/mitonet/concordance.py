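"""Proteome-transcriptome concordance analysis.

Microarray intensities are log2-transformed, quantile-normalized, and
filtered on detection p-values; per-gene mRNA log2 ratios (mtDNA-depleted
over parental) are joined with the protein log2 ratios and the joint 2-D
profiles are partitioned by k-means into five concordance groups: up_up,
down_down (positively correlated), up_down, down_up (negatively
correlated), and unchanged.  Cluster labels are assigned from centroid
geometry: a centroid is called up/down on an axis when it exceeds +/- delta
(default log2(1.2)), and the centroid closest to the origin is the
unchanged group.  Module-level summaries report mean +/- sd of linear
protein and mRNA abundance ratios, mirroring box-plot style reporting.

``pattern_agreement`` scores two independent classifications of the same
proteins (e.g. two proteomic platforms) as the percentage of shared ids
with identical regulation calls, plus an exact binomial test of the
agreement count against the chance-agreement rate implied by the two
marginal class distributions (the choice of binomial reference is a
convention of this package; no specific statistic is standard here).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .core_model import DOWN, UNCHANGED, UP

logger = logging.getLogger(__name__)

UP_UP = "up_up"
DOWN_DOWN = "down_down"
UP_DOWN = "up_down"
DOWN_UP = "down_up"
CONCORDANCE_GROUPS = (UP_UP, DOWN_DOWN, UP_DOWN, DOWN_UP, UNCHANGED)

DEFAULT_DELTA = math.log2(1.2)

RHO0 = "rho0"
RHO_PLUS = "rho_plus"


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force all sample columns to share one empirical distribution.

    Each column's values are replaced by the across-column means of the
    sorted values at the corresponding rank; tied values receive the mean
    of their target quantiles (mid-rank interpolation).  Intended for
    log2-scale intensities.
    """
    if matrix.empty:
        return matrix.copy()
    values = matrix.to_numpy(dtype=float)
    n = values.shape[0]
    sorted_means = np.sort(values, axis=0).mean(axis=1)
    positions = np.arange(1, n + 1, dtype=float)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        from scipy.stats import rankdata

        ranks = rankdata(values[:, j], method="average")
        out[:, j] = np.interp(ranks, positions, sorted_means)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def detection_filter(
    matrix: pd.DataFrame,
    detection_p: pd.DataFrame,
    conditions: Mapping[str, str],
    alpha: float = 0.05,
) -> Tuple[pd.DataFrame, int]:
    """Drop genes undetected throughout a condition.

    A gene is removed when its detection p-value exceeds ``alpha`` in every
    sample of at least one condition.  Returns the surviving matrix and the
    number of removed genes (also logged).
    """
    if matrix.empty:
        return matrix.copy(), 0
    if list(matrix.columns) != list(detection_p.columns) or not matrix.index.equals(
        detection_p.index
    ):
        raise ValueError("intensity and detection-p matrices are not aligned")
    removed = np.zeros(len(matrix), dtype=bool)
    for condition in sorted(set(conditions.values())):
        cols = [s for s in matrix.columns if conditions[s] == condition]
        if not cols:
            raise ValueError(f"condition {condition!r} has no samples")
        removed |= (detection_p[cols] > alpha).all(axis=1).to_numpy()
    n_removed = int(removed.sum())
    if n_removed:
        logger.info("detection filter removed %d genes (p > %g)", n_removed, alpha)
    return matrix.loc[~removed].copy(), n_removed


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at one."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def mrna_log2_ratios(
    log2_matrix: pd.DataFrame,
    conditions: Mapping[str, str],
    numerator: str = RHO0,
    denominator: str = RHO_PLUS,
) -> pd.Series:
    """Per-gene mRNA log2 ratio between the two conditions.

    The mean over all numerator/denominator replicate pairs of the log2
    difference, which equals the difference of per-condition means.
    """
    num_cols = [s for s in log2_matrix.columns if conditions[s] == numerator]
    den_cols = [s for s in log2_matrix.columns if conditions[s] == denominator]
    if not num_cols or not den_cols:
        raise ValueError("both conditions need at least one replicate")
    return log2_matrix[num_cols].mean(axis=1) - log2_matrix[den_cols].mean(axis=1)


def profile_table(
    abundance: pd.DataFrame,
    mrna_log2: Mapping[str, float],
) -> pd.DataFrame:
    """Join protein and mRNA log2 ratios on protein id.

    ``abundance`` needs ``protein_id`` and ``protein_ratio`` (linear scale)
    columns.  Proteins without an mRNA measurement are excluded with a
    logged count.  Returns columns protein_id, protein_log2, mrna_log2.
    """
    mrna = pd.Series(dict(mrna_log2), dtype=float)
    rows = []
    n_excluded = 0
    for pid, ratio in zip(abundance["protein_id"], abundance["protein_ratio"]):
        if pid in mrna.index and np.isfinite(mrna[pid]):
            rows.append((pid, math.log2(ratio), float(mrna[pid])))
        else:
            n_excluded += 1
    if n_excluded:
        logger.info("excluded %d proteins without mRNA measurements", n_excluded)
    return pd.DataFrame(rows, columns=["protein_id", "protein_log2", "mrna_log2"])


@dataclass(frozen=True)
class ConcordancePartition:
    """Labeled k-means partition of the 2-D expression profiles."""

    groups: Mapping[str, Tuple[str, ...]]
    centroids: Mapping[str, Tuple[float, float]]
    inertia: float
    seed: int

    def group_sizes(self) -> Dict[str, int]:
        return {g: len(ids) for g, ids in self.groups.items()}

    @property
    def n_positive(self) -> int:
        """Members whose protein and mRNA change in the same direction."""
        return len(self.groups[UP_UP]) + len(self.groups[DOWN_DOWN])

    @property
    def n_negative(self) -> int:
        return len(self.groups[UP_DOWN]) + len(self.groups[DOWN_UP])


def _label_centroids(
    centers: np.ndarray, delta: float
) -> Dict[int, str]:
    norms = np.linalg.norm(centers, axis=1)
    unchanged_idx = int(np.argmin(norms))
    labels: Dict[int, str] = {unchanged_idx: UNCHANGED}
    for i, (prot, mrna) in enumerate(centers):
        if i == unchanged_idx:
            continue
        if prot > delta and mrna > delta:
            label = UP_UP
        elif prot < -delta and mrna < -delta:
            label = DOWN_DOWN
        elif prot > delta and mrna < -delta:
            label = UP_DOWN
        elif prot < -delta and mrna > delta:
            label = DOWN_UP
        else:
            raise ValueError(
                f"centroid {tuple(np.round(centers[i], 4))} matches no concordance "
                f"label at delta={delta:.4f}; centroids: {np.round(centers, 4).tolist()}"
            )
        if label in labels.values():
            raise ValueError(
                f"two centroids map to {label}; centroids: {np.round(centers, 4).tolist()}"
            )
        labels[i] = label
    return labels


def kmeans_partition(
    profiles: pd.DataFrame,
    k: int = 5,
    seed: int = 0,
    delta: float = DEFAULT_DELTA,
    n_init: int = 10,
) -> ConcordancePartition:
    """Partition (protein_log2, mrna_log2) profiles into concordance groups.

    Runs k-means with ``n_init`` restarts (best inertia kept, deterministic
    given ``seed``) and labels the clusters from their centroid geometry as
    described in the module docstring.
    """
    if len(profiles) < k:
        raise ValueError(f"need at least k={k} profiles, got {len(profiles)}")
    x = profiles[["protein_log2", "mrna_log2"]].to_numpy(dtype=float)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    assignment = km.fit_predict(x)
    labels = _label_centroids(km.cluster_centers_, delta)
    groups: Dict[str, List[str]] = {g: [] for g in CONCORDANCE_GROUPS}
    for pid, cluster in zip(profiles["protein_id"], assignment):
        groups[labels[int(cluster)]].append(pid)
    centroids = {
        labels[i]: (float(c[0]), float(c[1]))
        for i, c in enumerate(km.cluster_centers_)
    }
    return ConcordancePartition(
        groups={g: tuple(ids) for g, ids in groups.items()},
        centroids=centroids,
        inertia=float(km.inertia_),
        seed=seed,
    )


def assign_groups(profiles: pd.DataFrame, partition: ConcordancePartition) -> pd.DataFrame:
    """Append the concordance-group column to a profile table."""
    lookup = {pid: g for g, ids in partition.groups.items() for pid in ids}
    out = profiles.copy()
    out["group"] = [lookup[p] for p in out["protein_id"]]
    return out


def module_expression_summary(
    modules: Sequence,
    profiles: pd.DataFrame,
) -> pd.DataFrame:
    """Per-module mean and sd of linear protein and mRNA abundance ratios.

    Only module members present in the profile table contribute; a module
    with no profiled member is omitted (logged).  Standard deviations use
    n - 1; a single-member module reports NaN sd.  ``protein_up`` and
    ``mrna_up`` flag whether the mean ratio exceeds one.
    """
    indexed = profiles.set_index("protein_id")
    rows = []
    for m in modules:
        members = [p for p in sorted(m.members) if p in indexed.index]
        if not members:
            logger.info("module %s has no profiled member; omitted", m.module_id)
            continue
        prot = np.power(2.0, indexed.loc[members, "protein_log2"].to_numpy())
        mrna = np.power(2.0, indexed.loc[members, "mrna_log2"].to_numpy())
        prot_sd = float(np.std(prot, ddof=1)) if len(members) > 1 else float("nan")
        mrna_sd = float(np.std(mrna, ddof=1)) if len(members) > 1 else float("nan")
        rows.append(
            (
                m.module_id,
                m.regulation_label,
                len(members),
                float(prot.mean()),
                prot_sd,
                float(mrna.mean()),
                mrna_sd,
                bool(prot.mean() > 1.0),
                bool(mrna.mean() > 1.0),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "module_id",
            "regulation_label",
            "n",
            "protein_mean",
            "protein_sd",
            "mrna_mean",
            "mrna_sd",
            "protein_up",
            "mrna_up",
        ],
    )


@dataclass(frozen=True)
class PatternAgreement:
    """Agreement between two regulation-class assignments."""

    n_shared: int
    n_agree: int
    percentage: float
    p_value: float


def pattern_agreement(
    patterns_a: Mapping[str, str],
    patterns_b: Mapping[str, str],
) -> PatternAgreement:
    """Score agreement of two classifications over their shared proteins.

    Returns the percentage of shared ids with identical class (two
    decimals) and a two-sided exact binomial test of the agreement count
    against the chance-agreement probability implied by the two marginal
    class distributions.
    """
    shared = sorted(set(patterns_a) & set(patterns_b))
    if not shared:
        raise ValueError("no shared protein ids between the two pattern maps")
    n = len(shared)
    n_agree = sum(1 for p in shared if patterns_a[p] == patterns_b[p])
    classes = sorted({patterns_a[p] for p in shared} | {patterns_b[p] for p in shared})
    chance = sum(
        (sum(patterns_a[p] == c for p in shared) / n)
        * (sum(patterns_b[p] == c for p in shared) / n)
        for c in classes
    )
    chance = min(max(chance, 1e-12), 1 - 1e-12)
    p = binomtest(n_agree, n, chance, alternative="two-sided").pvalue
    return PatternAgreement(
        n_shared=n,
        n_agree=n_agree,
        percentage=round(100.0 * n_agree / n, 2),
        p_value=float(p),
    )
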