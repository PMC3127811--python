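"""Functional network construction and intra/inter-regulatory link statistics.

The reliable proteins are assembled into a simple undirected graph whose
edges carry a confidence score in [0, 1] and a channel flag (physical or
functional association).  Analysis runs on the largest connected component.
Edges are categorized by the regulation classes of their endpoints:
*intra*-regulatory (up-up or down-down), *inter*-regulatory (up-down), or
*other* (at least one unchanged endpoint).  Per-protein link-type fractions
and same-class versus opposite-class shortest-path-length samples quantify
how strongly up- and down-regulated proteins segregate into their own
subnetworks; the two sample collections are compared with a Mann-Whitney U
test.

Shortest paths are unweighted breadth-first distances over all edges of the
major component; confidence scores are not used as edge lengths.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, List, Mapping, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core_model import DOWN, UP

logger = logging.getLogger(__name__)

INTRA = "intra"
INTER = "inter"
OTHER = "other"

TWO_SIDED = "two_sided"
LESS = "less"
GREATER = "greater"


def build_network(
    reliable_ids: Iterable[str],
    links: pd.DataFrame,
    classes: Mapping[str, str],
    score_min: float = 0.0,
) -> nx.Graph:
    """Induce the functional network on the reliable protein set.

    Keeps link rows whose endpoints are both reliable and whose confidence
    is at least ``score_min``; rows touching a non-reliable id are dropped
    (count logged).  Duplicate rows for the same unordered pair collapse to
    one edge keeping the maximum confidence (and that row's channel).  Every
    node carries its regulation class from ``classes``.
    """
    reliable = set(reliable_ids)
    if not reliable:
        raise ValueError("reliable_ids must be non-empty")
    g = nx.Graph()
    for pid in sorted(reliable):
        try:
            g.add_node(pid, regulation=classes[pid])
        except KeyError:
            raise KeyError(f"no regulation class for protein {pid!r}") from None
    n_dropped = 0
    for a, b, conf, channel in zip(
        links["protein_a"], links["protein_b"], links["confidence"], links["channel"]
    ):
        if a not in reliable or b not in reliable:
            n_dropped += 1
            continue
        if a == b or conf < score_min:
            continue
        if g.has_edge(a, b) and g[a][b]["confidence"] >= conf:
            continue
        g.add_edge(a, b, confidence=float(conf), channel=channel)
    if n_dropped:
        logger.info("dropped %d link rows touching non-reliable proteins", n_dropped)
    return g


def largest_component(net: nx.Graph) -> Tuple[nx.Graph, List[str]]:
    """Extract the major connected component.

    Returns the induced subgraph on the largest component and the sorted
    list of excluded node ids.  Size ties break toward the component
    containing the lexicographically smallest member id.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("network is empty")
    components = list(nx.connected_components(net))
    major = max(components, key=lambda c: (len(c), ReverseStr(min(c))))
    excluded = sorted(set(net.nodes) - major)
    return net.subgraph(major).copy(), excluded


class ReverseStr(str):
    """String with reversed ordering, for min-id tie-breaking inside max()."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):  # pragma: no cover - trivial
        return str.__lt__(self, other)


@dataclass(frozen=True)
class LinkCategorySummary:
    """Edge counts by regulatory category."""

    n_intra: int
    n_inter: int
    n_other: int

    @property
    def n_total(self) -> int:
        return self.n_intra + self.n_inter + self.n_other

    @property
    def n_regulatory(self) -> int:
        """Links with both endpoints up- or down-regulated."""
        return self.n_intra + self.n_inter

    @property
    def intra_pct_of_regulatory(self) -> Optional[float]:
        """Intra-regulatory percentage of regulatory links (two decimals).

        ``None`` when there are no regulatory links.
        """
        if self.n_regulatory == 0:
            return None
        return round(100.0 * self.n_intra / self.n_regulatory, 2)


def edge_category(class_a: str, class_b: str) -> str:
    if {class_a, class_b} <= {UP} or {class_a, class_b} <= {DOWN}:
        return INTRA
    if {class_a, class_b} == {UP, DOWN}:
        return INTER
    return OTHER


def categorize_links(net: nx.Graph) -> Tuple[LinkCategorySummary, pd.DataFrame]:
    """Label every edge intra / inter / other and summarize the counts."""
    rows = []
    for a, b, data in net.edges(data=True):
        x, y = sorted((a, b))
        cat = edge_category(net.nodes[x]["regulation"], net.nodes[y]["regulation"])
        rows.append(
            (x, y, data.get("confidence", 1.0), data.get("channel", ""), cat)
        )
    table = pd.DataFrame(
        rows, columns=["protein_a", "protein_b", "confidence", "channel", "category"]
    ).sort_values(["protein_a", "protein_b"], ignore_index=True)
    counts = table["category"].value_counts() if len(table) else {}
    summary = LinkCategorySummary(
        n_intra=int(counts.get(INTRA, 0)),
        n_inter=int(counts.get(INTER, 0)),
        n_other=int(counts.get(OTHER, 0)),
    )
    return summary, table


def link_fraction_samples(net: nx.Graph) -> Tuple[List[float], List[float]]:
    """Per-protein intra and inter link fractions.

    For every up- or down-regulated node with at least one regulatory edge
    (an edge to another regulated node), computes the fraction of its
    regulatory edges that are intra- and inter-regulatory.  The denominator
    is regulatory edges only, so the two fractions sum to one per node.
    Returns the two per-node fraction collections (intra, inter).
    """
    intra_fracs: List[float] = []
    inter_fracs: List[float] = []
    for node, data in net.nodes(data=True):
        cls = data["regulation"]
        if cls not in (UP, DOWN):
            continue
        n_intra = n_inter = 0
        for nb in net.neighbors(node):
            nb_cls = net.nodes[nb]["regulation"]
            if nb_cls == cls:
                n_intra += 1
            elif nb_cls in (UP, DOWN):
                n_inter += 1
        n_reg = n_intra + n_inter
        if n_reg == 0:
            continue
        intra_fracs.append(n_intra / n_reg)
        inter_fracs.append(n_inter / n_reg)
    return intra_fracs, inter_fracs


@dataclass(frozen=True)
class PairPathSamples:
    """Shortest-path-length samples for regulated protein pairs."""

    same_class: Tuple[int, ...]
    opposite_class: Tuple[int, ...]


def shortest_path_samples(net: nx.Graph, pairs: str = "all") -> PairPathSamples:
    """Shortest path lengths between regulated proteins, binned by class.

    Breadth-first (unweighted) distances over all edges of ``net`` for every
    unordered pair of up/down-regulated nodes.  Same-class pairs are up-up
    and down-down; opposite-class pairs are up-down.  With ``pairs="all"``
    (default) every connected regulated pair contributes; with
    ``pairs="adjacent"`` only directly linked pairs (length 1) do.
    """
    if pairs not in ("all", "adjacent"):
        raise ValueError(f"pairs must be 'all' or 'adjacent', got {pairs!r}")
    regulated = sorted(
        n for n, d in net.nodes(data=True) if d["regulation"] in (UP, DOWN)
    )
    if len(regulated) < 2:
        raise ValueError("need at least two regulated proteins for path samples")
    same: List[int] = []
    opposite: List[int] = []
    if pairs == "adjacent":
        for a, b in net.edges():
            ca, cb = net.nodes[a]["regulation"], net.nodes[b]["regulation"]
            if ca in (UP, DOWN) and cb in (UP, DOWN):
                (same if ca == cb else opposite).append(1)
    else:
        index = {n: i for i, n in enumerate(regulated)}
        for a in regulated:
            lengths = nx.single_source_shortest_path_length(net, a)
            ca = net.nodes[a]["regulation"]
            for b, dist in lengths.items():
                if b not in index or index[b] <= index[a]:
                    continue
                cb = net.nodes[b]["regulation"]
                (same if ca == cb else opposite).append(dist)
    if not same and not opposite:
        raise ValueError("no connected regulated pairs in the network")
    return PairPathSamples(same_class=tuple(same), opposite_class=tuple(opposite))


@dataclass(frozen=True)
class MannWhitneyResult:
    """Mann-Whitney U statistic (of the first sample) and its p-value."""

    U: float
    p_value: float
    alternative: str
    method: str


def _u_statistic(ranks: np.ndarray, idx_x: Sequence[int], n_x: int) -> float:
    return float(ranks[list(idx_x)].sum() - n_x * (n_x + 1) / 2.0)


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = TWO_SIDED,
    exact_max: int = 12,
) -> MannWhitneyResult:
    """Rank-sum Mann-Whitney U test with mid-rank tie handling.

    For pooled sizes up to ``exact_max`` the p-value is computed by exact
    enumeration of all group labelings of the pooled sample (correct under
    ties); otherwise a normal approximation with tie-corrected variance and
    a 0.5 continuity correction is used.  ``alternative="less"`` tests that
    ``x`` is stochastically smaller than ``y``; ``"greater"`` the reverse.

    A pooled sample with a single distinct value carries no rank
    information: the test warns and returns p = 1.
    """
    if alternative not in (TWO_SIDED, LESS, GREATER):
        raise ValueError(f"unknown alternative {alternative!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n_x, n_y = x.size, y.size
    n = n_x + n_y
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    u_obs = _u_statistic(ranks, range(n_x), n_x)

    if np.unique(pooled).size == 1:
        warnings.warn("constant pooled sample; Mann-Whitney p set to 1")
        return MannWhitneyResult(u_obs, 1.0, alternative, "degenerate")

    if n <= exact_max:
        us = np.array(
            [
                _u_statistic(ranks, idx, n_x)
                for idx in itertools.combinations(range(n), n_x)
            ]
        )
        eps = 1e-9
        p_less = float(np.mean(us <= u_obs + eps))
        p_greater = float(np.mean(us >= u_obs - eps))
        if alternative == LESS:
            p = p_less
        elif alternative == GREATER:
            p = p_greater
        else:
            p = min(1.0, 2.0 * min(p_less, p_greater))
        return MannWhitneyResult(u_obs, p, alternative, "exact")

    mu = n_x * n_y / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n_x * n_y / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        warnings.warn("zero rank variance; Mann-Whitney p set to 1")
        return MannWhitneyResult(u_obs, 1.0, alternative, "degenerate")
    sd = math.sqrt(var)
    from scipy.stats import norm

    if alternative == LESS:
        p = float(norm.cdf((u_obs - mu + 0.5) / sd))
    elif alternative == GREATER:
        p = float(norm.sf((u_obs - mu - 0.5) / sd))
    else:
        z = (abs(u_obs - mu) - 0.5) / sd
        p = float(min(1.0, 2.0 * norm.sf(z)))
    return MannWhitneyResult(u_obs, p, alternative, "normal")
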