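"""Functional-module detection by average-linkage clustering and enrichment.

Modules are found on the major network component by hierarchical
average-linkage (UPGMA) clustering with edge confidence scores as the
similarity measure: entries of the similarity matrix are edge confidences,
zero for absent edges, one on the diagonal.  Agglomeration merges the pair
of clusters with the greatest unweighted mean cross-pair similarity and
stops when that best mean falls below a cut ``tau``; clusters smaller than
``min_size`` go to an unassigned pool.

A cluster becomes a functional module when it is enriched (one-sided
hypergeometric upper tail, p < 0.01) both for an annotation term and for
one regulation class; the minimum-p enriched term is the module's
representative function and the enriched class its regulation label.  The
background for both tests is the clustered universe (the major-component
proteins), restricted for term enrichment to proteins carrying at least one
term.  Annotations are flat term sets; term-hierarchy propagation is out of
scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .core_model import DOWN, UP

logger = logging.getLogger(__name__)

# A merge cut on mean cross-pair similarity.  Because absent edges count as
# similarity 0, the expected within-module mean similarity is roughly the
# within-module edge density times the mean edge confidence; the cut must sit
# between that and the (much smaller) between-module expectation.  0.1 works
# across realistic densities; sparser networks need a lower cut.
DEFAULT_TAU = 0.1
DEFAULT_MIN_SIZE = 3
DEFAULT_ALPHA = 0.01


def similarity_from_network(
    net: nx.Graph, nodes: Optional[Sequence[str]] = None
) -> Tuple[np.ndarray, List[str]]:
    """Confidence-score similarity matrix of a functional network.

    Returns a symmetric matrix with edge confidences off-diagonal (0 where
    no edge), ones on the diagonal, and the node ordering used.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("network is empty")
    order = list(nodes) if nodes is not None else sorted(net.nodes)
    index = {n: i for i, n in enumerate(order)}
    s = np.zeros((len(order), len(order)))
    np.fill_diagonal(s, 1.0)
    for a, b, data in net.edges(data=True):
        if a in index and b in index:
            i, j = index[a], index[b]
            s[i, j] = s[j, i] = float(data.get("confidence", 1.0))
    return s, order


@dataclass(frozen=True)
class ClusterSet:
    """Result of a dendrogram cut: module candidates plus an unassigned pool.

    ``merge_similarities`` records the mean similarity of each performed
    merge, in merge order (non-increasing for average linkage).
    """

    clusters: Tuple[FrozenSet[str], ...]
    unassigned: FrozenSet[str]
    merge_similarities: Tuple[float, ...]

    @property
    def members(self) -> FrozenSet[str]:
        out = set(self.unassigned)
        for c in self.clusters:
            out |= c
        return frozenset(out)


def upgma_cluster(
    sim: np.ndarray,
    labels: Sequence[str],
    tau: float = DEFAULT_TAU,
    min_size: int = DEFAULT_MIN_SIZE,
) -> ClusterSet:
    """Average-linkage clustering of a similarity matrix with a cut at tau.

    Clusters merge while the best unweighted mean cross-pair similarity is
    at least ``tau`` (inclusive); the cut is equivalent to average-linkage
    clustering of the dissimilarity 1 - s cut at height 1 - tau.  Flat
    clusters with fewer than ``min_size`` members are returned in the
    unassigned pool instead of as module candidates.
    """
    if not (0.0 < tau <= 1.0):
        raise ValueError(f"tau must lie in (0, 1], got {tau}")
    if min_size < 2:
        raise ValueError(f"min_size must be >= 2, got {min_size}")
    sim = np.asarray(sim, dtype=float)
    n = sim.shape[0]
    if sim.shape != (n, n) or n != len(labels):
        raise ValueError("similarity matrix shape does not match labels")
    if not np.allclose(sim, sim.T, atol=1e-12):
        raise ValueError("similarity matrix is not symmetric")
    if sim.min() < -1e-12 or sim.max() > 1 + 1e-12:
        raise ValueError("similarity values must lie in [0, 1]")
    if n == 1:
        return ClusterSet((), frozenset(labels), ())

    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    cut = 1.0 - tau + 1e-12
    flat = fcluster(z, t=cut, criterion="distance")
    merge_sims = tuple(1.0 - h for h in z[:, 2] if h <= cut)

    groups: Dict[int, set] = {}
    for lab, cid in zip(labels, flat):
        groups.setdefault(int(cid), set()).add(lab)
    clusters = []
    unassigned: set = set()
    for members in groups.values():
        if len(members) >= min_size:
            clusters.append(frozenset(members))
        else:
            unassigned |= members
    clusters.sort(key=lambda c: (-len(c), min(c)))
    return ClusterSet(tuple(clusters), frozenset(unassigned), merge_sims)


def hypergeometric_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    ``X`` counts successes in a draw of ``n`` without replacement from a
    population of ``N`` containing ``K`` successes.  Computed via the
    survival function, which is numerically stable for small tails.
    """
    if not (0 <= k <= n <= N and 0 <= K <= N):
        raise ValueError(
            f"inconsistent counts: k={k}, K={K}, n={n}, N={N}"
        )
    return float(hypergeom.sf(k - 1, N, K, n))


@dataclass(frozen=True)
class EnrichmentResult:
    """One term (or regulation class) tested for over-representation."""

    label: str
    k: int
    K: int
    n: int
    N: int
    p_value: float


def term_enrichment(
    cluster: Iterable[str],
    annotations: Mapping[str, FrozenSet[str]],
    background: Iterable[str],
) -> List[EnrichmentResult]:
    """Per-term one-sided hypergeometric enrichment of a cluster.

    ``background`` should be the clustered-universe proteins carrying at
    least one term; cluster members outside it are ignored.  Terms with
    fewer than two annotated members in the cluster are not tested.
    Results are sorted by ascending p (ties by term id); the first entry is
    the representative term.
    """
    bg = {p for p in background if annotations.get(p)}
    members = set(cluster) & bg
    if not members:
        return []
    n, N = len(members), len(bg)
    term_in_cluster: Dict[str, int] = {}
    for p in members:
        for t in annotations[p]:
            term_in_cluster[t] = term_in_cluster.get(t, 0) + 1
    term_in_bg: Dict[str, int] = {}
    for p in bg:
        for t in annotations[p]:
            term_in_bg[t] = term_in_bg.get(t, 0) + 1
    results = [
        EnrichmentResult(
            t, k, term_in_bg[t], n, N, hypergeometric_tail(k, term_in_bg[t], n, N)
        )
        for t, k in term_in_cluster.items()
        if k >= 2
    ]
    results.sort(key=lambda r: (r.p_value, r.label))
    return results


def regulation_enrichment(
    cluster: Iterable[str],
    classes: Mapping[str, str],
    background: Iterable[str],
    alpha: float = DEFAULT_ALPHA,
) -> Optional[Tuple[str, float]]:
    """Test a cluster for enrichment of up- or down-regulated proteins.

    Computes the hypergeometric upper-tail p for each direction over the
    clustered-universe background; returns the direction with the smaller
    p if it is below ``alpha``, else ``None``.  Exact p ties break toward
    the direction with more members in the cluster (logged).
    """
    bg = set(background)
    members = set(cluster) & bg
    if not members:
        return None
    n, N = len(members), len(bg)
    k_up = sum(1 for p in members if classes[p] == UP)
    k_down = sum(1 for p in members if classes[p] == DOWN)
    K_up = sum(1 for p in bg if classes[p] == UP)
    K_down = sum(1 for p in bg if classes[p] == DOWN)
    p_up = hypergeometric_tail(k_up, K_up, n, N)
    p_down = hypergeometric_tail(k_down, K_down, n, N)
    if p_up == p_down:
        label, p = (UP, p_up) if k_up >= k_down else (DOWN, p_down)
        logger.info("regulation enrichment tie; broke toward %s (k=%d)", label, max(k_up, k_down))
    elif p_up < p_down:
        label, p = UP, p_up
    else:
        label, p = DOWN, p_down
    return (label, p) if p < alpha else None


@dataclass(frozen=True)
class FunctionalModule:
    """A detected cluster with its function and regulation labels."""

    module_id: str
    members: FrozenSet[str]
    representative_term: str
    term_p: float
    regulation_label: str
    regulation_p: float
    n_opposing: int


def assemble_modules(
    cluster_set: ClusterSet,
    annotations: Mapping[str, FrozenSet[str]],
    classes: Mapping[str, str],
    background: Iterable[str],
    alpha: float = DEFAULT_ALPHA,
    bh_adjust_terms: bool = False,
) -> List[FunctionalModule]:
    """Promote clusters to functional modules via the double enrichment rule.

    A cluster qualifies when its best term-enrichment p and its regulation
    enrichment p are both below ``alpha``.  With ``bh_adjust_terms`` the
    term p-values of each cluster are Benjamini-Hochberg adjusted before
    the cut (off by default).  ``n_opposing`` counts members whose class
    opposes the module label.
    """
    background = set(background)
    modules: List[FunctionalModule] = []
    for i, cluster in enumerate(cluster_set.clusters):
        terms = term_enrichment(cluster, annotations, background)
        if not terms:
            continue
        term_ps = [r.p_value for r in terms]
        if bh_adjust_terms:
            term_ps = list(multipletests(term_ps, method="fdr_bh")[1])
        if term_ps[0] >= alpha:
            continue
        reg = regulation_enrichment(cluster, classes, background, alpha=alpha)
        if reg is None:
            continue
        label, reg_p = reg
        opposite = DOWN if label == UP else UP
        n_opposing = sum(1 for p in cluster if classes.get(p) == opposite)
        modules.append(
            FunctionalModule(
                module_id=f"M{len(modules) + 1:02d}",
                members=cluster,
                representative_term=terms[0].label,
                term_p=float(term_ps[0]),
                regulation_label=label,
                regulation_p=float(reg_p),
                n_opposing=n_opposing,
            )
        )
    return modules


def module_coverage(
    modules: Sequence[FunctionalModule],
    classes: Mapping[str, str],
    background: Iterable[str],
) -> Dict[str, Dict[str, float]]:
    """Fraction of up/down proteins captured by same-label modules.

    For each direction, counts background proteins of that class belonging
    to a module with the matching regulation label, and reports the count,
    the class total, and the percentage (two decimals, ``None`` when the
    class is empty).
    """
    background = set(background)
    out: Dict[str, Dict[str, float]] = {}
    for direction in (UP, DOWN):
        total = {p for p in background if classes[p] == direction}
        covered = set()
        for m in modules:
            if m.regulation_label == direction:
                covered |= {p for p in m.members if p in total}
        pct = round(100.0 * len(covered) / len(total), 2) if total else None
        out[direction] = {"covered": len(covered), "total": len(total), "percent": pct}
    return out


def modules_table(modules: Sequence[FunctionalModule]) -> pd.DataFrame:
    """Long-format module report: one row per module member."""
    rows = []
    for m in modules:
        for member in sorted(m.members):
            rows.append(
                (
                    m.module_id,
                    member,
                    m.regulation_label,
                    m.representative_term,
                    m.term_p,
                    m.regulation_p,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "module_id",
            "member_id",
            "regulation_label",
            "representative_term",
            "term_p",
            "regulation_p",
        ],
    )
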