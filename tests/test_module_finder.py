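"""Average-linkage module detection and hypergeometric enrichment."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest
from scipy.stats import hypergeom

from mitonet.module_finder import (
    ClusterSet,
    FunctionalModule,
    assemble_modules,
    hypergeometric_tail,
    module_coverage,
    regulation_enrichment,
    similarity_from_network,
    term_enrichment,
    upgma_cluster,
)


def naive_upgma(sim, labels, tau):
    """O(n^3) greedy reference: repeatedly merge the best-average pair."""
    clusters = [frozenset([lab]) for lab in labels]
    index = {lab: i for i, lab in enumerate(labels)}
    merges = []
    while len(clusters) > 1:
        best, best_pair = -1.0, None
        for i, j in itertools.combinations(range(len(clusters)), 2):
            vals = [
                sim[index[a]][index[b]] for a in clusters[i] for b in clusters[j]
            ]
            avg = sum(vals) / len(vals)
            if avg > best + 1e-12:
                best, best_pair = avg, (i, j)
        if best < tau - 1e-12:
            break
        i, j = best_pair
        merged = clusters[i] | clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
        merges.append(best)
    return clusters, merges


def random_similarity(rng, n):
    s = rng.uniform(0, 1, size=(n, n))
    s = (s + s.T) / 2
    np.fill_diagonal(s, 1.0)
    return s


def test_similarity_matrix_entries():
    g = nx.Graph()
    g.add_node("A", regulation="up")
    g.add_node("B", regulation="up")
    g.add_node("C", regulation="down")
    g.add_edge("A", "B", confidence=0.8)
    s, order = similarity_from_network(g)
    i, j, k = order.index("A"), order.index("B"), order.index("C")
    assert s[i][j] == 0.8
    assert s[i][k] == 0.0  # absent edge -> similarity 0
    assert s[i][i] == 1.0
    assert np.allclose(s, s.T)


def test_upgma_simple_pair():
    labels = ["A", "B", "C"]
    s = np.array([[1.0, 0.9, 0.1], [0.9, 1.0, 0.1], [0.1, 0.1, 1.0]])
    cs = upgma_cluster(s, labels, tau=0.5, min_size=2)
    assert cs.clusters == (frozenset({"A", "B"}),)
    assert cs.unassigned == {"C"}


def test_upgma_tau_one_no_merges():
    labels = ["A", "B", "C"]
    s = np.array([[1.0, 0.9, 0.2], [0.9, 1.0, 0.2], [0.2, 0.2, 1.0]])
    cs = upgma_cluster(s, labels, tau=1.0, min_size=2)
    assert cs.clusters == ()
    assert cs.unassigned == {"A", "B", "C"}


def test_upgma_invalid_tau():
    s = np.eye(2)
    for tau in (0.0, -0.5, 1.5):
        with pytest.raises(ValueError):
            upgma_cluster(s, ["A", "B"], tau=tau)


def test_upgma_merge_heights_non_increasing(rng):
    for _ in range(20):
        s = random_similarity(rng, 7)
        cs = upgma_cluster(s, list("ABCDEFG"), tau=0.05, min_size=2)
        sims = list(cs.merge_similarities)
        assert all(a >= b - 1e-9 for a, b in zip(sims, sims[1:]))


def test_upgma_matches_naive_reference(rng):
    """Flat clusters equal a greedy O(n^3) reference on random matrices."""
    labels = list("ABCDEF")
    for _ in range(25):
        s = random_similarity(rng, 6)
        tau = float(rng.uniform(0.2, 0.9))
        cs = upgma_cluster(s, labels, tau=tau, min_size=2)
        ref_clusters, ref_merges = naive_upgma(s, labels, tau)
        ours = set(cs.clusters) | {frozenset([x]) for x in cs.unassigned}
        assert ours == set(ref_clusters)
        assert np.allclose(
            sorted(cs.merge_similarities), sorted(ref_merges), atol=1e-9
        )


def test_hypergeometric_examples():
    # 2+ white of 3 drawn from 10 with 4 white: (C(4,2)C(6,1)+C(4,3))/C(10,3)
    assert hypergeometric_tail(2, 4, 3, 10) == pytest.approx(40 / 120)
    assert hypergeometric_tail(0, 4, 3, 10) == 1.0
    assert hypergeometric_tail(5, 5, 5, 5) == pytest.approx(1.0)


def test_hypergeometric_inconsistent_counts():
    for bad in [(3, 2, 2, 10), (1, 2, 3, 2), (-1, 2, 3, 10)]:
        with pytest.raises(ValueError):
            hypergeometric_tail(*bad)


def test_hypergeometric_matches_enumeration_small():
    for N in range(1, 9):
        for K in range(N + 1):
            for n in range(N + 1):
                for k in range(min(n, K) + 1):
                    expected = sum(
                        math.comb(K, i) * math.comb(N - K, n - i)
                        for i in range(k, min(n, K) + 1)
                    ) / math.comb(N, n)
                    assert hypergeometric_tail(k, K, n, N) == pytest.approx(expected)


def test_term_enrichment_direct_arithmetic():
    """Cluster of 5 all term-T in background of 100 with 10 T-carriers."""
    background = [f"P{i}" for i in range(100)]
    annotations = {p: frozenset({"OTHER"}) for p in background}
    for p in background[:10]:
        annotations[p] = frozenset({"T", "OTHER"})
    cluster = background[:5]
    results = term_enrichment(cluster, annotations, background)
    best = results[0]
    assert best.label == "T"
    expected = math.comb(10, 5) / math.comb(100, 5)
    # P(X>=5) with n=5 draws: only the all-T draw contributes
    assert best.p_value == pytest.approx(expected, rel=1e-9)


def test_term_annotating_all_background_is_null():
    background = [f"P{i}" for i in range(20)]
    annotations = {p: frozenset({"T"}) for p in background}
    results = term_enrichment(background[:5], annotations, background)
    assert results[0].p_value == pytest.approx(1.0)


def test_cluster_without_annotations_empty():
    assert term_enrichment(["A"], {"A": frozenset()}, ["A"]) == []


def test_terms_with_single_member_not_tested():
    background = ["A", "B", "C", "D"]
    annotations = {
        "A": frozenset({"T1"}),
        "B": frozenset({"T2"}),
        "C": frozenset({"T2"}),
        "D": frozenset({"T2"}),
    }
    results = term_enrichment(["A", "B", "C"], annotations, background)
    assert {r.label for r in results} == {"T2"}


def test_hypergeometric_type_one_error_rate(rng):
    """Under random draws the tail p rejects at most ~alpha of the time."""
    N, K, n = 200, 40, 25
    ks = hypergeom.rvs(N, K, n, size=10_000, random_state=1234)
    ps = np.array([hypergeometric_tail(int(k), K, n, N) for k in ks])
    rate = float(np.mean(ps < 0.01))
    # discrete test: valid (<= alpha up to binomial noise) and non-degenerate
    assert rate <= 0.01 + 3 * math.sqrt(0.01 * 0.99 / 10_000)


def test_regulation_enrichment_all_up_cluster():
    background = [f"P{i}" for i in range(40)]
    classes = {p: ("up" if i < 20 else "down") for i, p in enumerate(background)}
    label, p = regulation_enrichment(background[:8], classes, background)
    assert label == "up"
    assert p < 0.01


def test_regulation_enrichment_background_composition_is_null():
    background = [f"P{i}" for i in range(40)]
    classes = {p: ("up" if i % 2 == 0 else "down") for i, p in enumerate(background)}
    cluster = background[:10]  # 5 up, 5 down, mirrors background
    assert regulation_enrichment(cluster, classes, background) is None


def test_regulation_enrichment_tie_is_deterministic():
    # symmetric composition forces p_up == p_down; the tie must resolve
    # deterministically rather than by dict order
    background = ["A", "B", "C", "D"]
    classes = {"A": "up", "B": "up", "C": "down", "D": "down"}
    result = regulation_enrichment(["A", "C"], classes, background, alpha=1.0)
    assert result is not None
    label, p = result
    assert label == "up"  # equal counts break toward up by convention
    assert p == pytest.approx(5 / 6)


def test_assemble_requires_both_enrichments():
    background = [f"P{i}" for i in range(40)]
    classes = {p: ("up" if i < 10 else "unchanged") for i, p in enumerate(background)}
    annotations = {p: frozenset({"T"} if i < 10 else {"X"}) for i, p in enumerate(background)}
    cs = ClusterSet(
        clusters=(frozenset(background[:10]), frozenset(background[20:30])),
        unassigned=frozenset(),
        merge_similarities=(),
    )
    modules = assemble_modules(cs, annotations, classes, background)
    assert len(modules) == 1
    assert modules[0].regulation_label == "up"
    assert modules[0].representative_term == "T"
    assert modules[0].n_opposing == 0


def test_no_passing_cluster_gives_empty_list():
    background = ["A", "B", "C", "D"]
    classes = {p: "unchanged" for p in background}
    annotations = {p: frozenset({"T"}) for p in background}
    cs = ClusterSet((frozenset(background),), frozenset(), ())
    assert assemble_modules(cs, annotations, classes, background) == []


def _module(mid, members, label):
    return FunctionalModule(mid, frozenset(members), "T", 1e-5, label, 1e-5, 0)


def test_coverage_percentages_at_study_scale():
    """59 of 89 up covered -> 66.29%; 138 of 175 down covered -> 78.86%."""
    ups = [f"U{i}" for i in range(89)]
    downs = [f"D{i}" for i in range(175)]
    others = [f"N{i}" for i in range(100)]
    classes = {**{p: "up" for p in ups}, **{p: "down" for p in downs}, **{p: "unchanged" for p in others}}
    modules = [_module("M1", ups[:59], "up"), _module("M2", downs[:138], "down")]
    cov = module_coverage(modules, classes, ups + downs + others)
    assert cov["up"] == {"covered": 59, "total": 89, "percent": 66.29}
    assert cov["down"] == {"covered": 138, "total": 175, "percent": 78.86}
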