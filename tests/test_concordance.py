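"""Expression preprocessing, concordance clustering, and pattern agreement."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitonet.concordance import (
    ConcordancePartition,
    bh_adjust,
    detection_filter,
    kmeans_partition,
    module_expression_summary,
    mrna_log2_ratios,
    pattern_agreement,
    profile_table,
    quantile_normalize,
)
from mitonet.module_finder import FunctionalModule


def brute_force_bh(p):
    """Step-up rule applied literally: q_(i) = min_{j>=i} p_(j) * m / j."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        running = min(running, p[i] * m / (rank + 1))
        q[i] = running
    return q


def test_quantile_normalize_fixed_point():
    df = pd.DataFrame({"s1": [1.0, 3.0, 2.0], "s2": [1.0, 3.0, 2.0]})
    out = quantile_normalize(df)
    pd.testing.assert_frame_equal(out, df)


def test_quantile_normalize_rank_means():
    df = pd.DataFrame({"s1": [1.0, 3.0], "s2": [2.0, 4.0]})
    out = quantile_normalize(df)
    assert list(out["s1"]) == [1.5, 3.5]
    assert list(out["s2"]) == [1.5, 3.5]


def test_quantile_normalize_identical_sorted_columns():
    rng = np.random.default_rng(5)
    df = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
    out = quantile_normalize(df)
    ref = np.sort(out["a"].to_numpy())
    for col in "bcd":
        assert np.allclose(np.sort(out[col].to_numpy()), ref)
    assert np.allclose(out.mean(axis=0), out.mean(axis=0).iloc[0])


def test_quantile_normalize_ties_get_mean_quantile():
    df = pd.DataFrame({"s1": [1.0, 1.0, 5.0], "s2": [2.0, 3.0, 4.0]})
    out = quantile_normalize(df)
    sorted_means = np.sort(df.to_numpy(), axis=0).mean(axis=1)  # [1.5, 2.0, 4.5]
    expected_tie = (sorted_means[0] + sorted_means[1]) / 2
    assert out["s1"].iloc[0] == pytest.approx(expected_tie)
    assert out["s1"].iloc[1] == pytest.approx(expected_tie)


def _expr(values, detection, samples=("rho0_1", "rho0_2", "rho_plus_1", "rho_plus_2")):
    genes = [f"g{i}" for i in range(len(values))]
    m = pd.DataFrame(values, index=genes, columns=samples)
    d = pd.DataFrame(detection, index=genes, columns=samples)
    conditions = {s: ("rho0" if s.startswith("rho0") else "rho_plus") for s in samples}
    return m, d, conditions


def test_detection_filter_keeps_detected():
    m, d, cond = _expr([[1, 1, 1, 1]], [[0.001] * 4])
    kept, n = detection_filter(m, d, cond)
    assert len(kept) == 1 and n == 0


def test_detection_filter_removes_undetected_everywhere():
    m, d, cond = _expr([[1, 1, 1, 1]], [[0.5] * 4])
    kept, n = detection_filter(m, d, cond)
    assert len(kept) == 0 and n == 1


def test_detection_filter_removes_condition_dropout():
    # undetected in every rho0 sample, detected in rho_plus
    m, d, cond = _expr([[1, 1, 1, 1]], [[0.5, 0.6, 0.01, 0.01]])
    kept, n = detection_filter(m, d, cond)
    assert len(kept) == 0


def test_detection_filter_keeps_partial_detection():
    # detected in at least one sample of each condition
    m, d, cond = _expr([[1, 1, 1, 1]], [[0.5, 0.01, 0.5, 0.01]])
    kept, n = detection_filter(m, d, cond)
    assert len(kept) == 1


def test_detection_filter_empty_matrix():
    m, d, cond = _expr(np.empty((0, 4)), np.empty((0, 4)))
    kept, n = detection_filter(m, d, cond)
    assert kept.empty and n == 0


def test_bh_examples():
    assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
    assert np.allclose(bh_adjust([0.2]), [0.2])
    assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.2])


@settings(deadline=None, derandomize=True, max_examples=50)
@given(
    st.lists(
        st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
        min_size=1,
        max_size=200,
    )
)
def test_bh_matches_brute_force(p):
    assert np.allclose(bh_adjust(p), brute_force_bh(np.asarray(p)))


def test_mrna_ratio_is_difference_of_condition_means():
    m, _, cond = _expr([[3.0, 5.0, 1.0, 1.0]], [[0.0] * 4])
    ratios = mrna_log2_ratios(m, cond)
    assert ratios.iloc[0] == pytest.approx(4.0 - 1.0)


def test_profile_table_log2_join():
    abundance = pd.DataFrame({"protein_id": ["A", "B"], "protein_ratio": [2.0, 4.0]})
    profiles = profile_table(abundance, {"A": 1.0})
    assert len(profiles) == 1  # B lacks an mRNA measurement
    assert profiles["protein_log2"].iloc[0] == pytest.approx(1.0)
    assert profiles["mrna_log2"].iloc[0] == pytest.approx(1.0)


def test_profile_table_preserves_counts():
    abundance = pd.DataFrame(
        {"protein_id": list("ABCD"), "protein_ratio": [2.0, 0.5, 1.0, 3.0]}
    )
    mrna = {"A": 0.1, "C": -0.2}
    profiles = profile_table(abundance, mrna)
    assert len(profiles) + 2 == len(abundance)


def _planted_profiles(rng, n_per=40, sd=0.1, sep=2.0):
    centers = {
        "up_up": (sep, sep),
        "down_down": (-sep, -sep),
        "up_down": (sep, -sep),
        "down_up": (-sep, sep),
        "unchanged": (0.0, 0.0),
    }
    rows, planted = [], {}
    for g, (cx, cy) in centers.items():
        for i in range(n_per):
            pid = f"{g}_{i}"
            rows.append((pid, cx + rng.normal(0, sd), cy + rng.normal(0, sd)))
            planted[pid] = g
    return pd.DataFrame(rows, columns=["protein_id", "protein_log2", "mrna_log2"]), planted


def test_kmeans_recovers_well_separated_groups(rng):
    profiles, planted = _planted_profiles(rng)
    part = kmeans_partition(profiles, seed=0)
    assign = {p: g for g, ids in part.groups.items() for p in ids}
    assert all(assign[p] == g for p, g in planted.items())


def test_kmeans_deterministic_given_seed(rng):
    profiles, _ = _planted_profiles(rng, sd=0.4)
    a = kmeans_partition(profiles, seed=3)
    b = kmeans_partition(profiles, seed=3)
    assert a.groups == b.groups
    assert a.inertia == b.inertia


def test_kmeans_too_few_points_rejected():
    df = pd.DataFrame(
        {"protein_id": ["A"], "protein_log2": [0.0], "mrna_log2": [0.0]}
    )
    with pytest.raises(ValueError, match="at least"):
        kmeans_partition(df)


def test_kmeans_unlabelable_geometry_names_centroids(rng):
    # five clouds all in the upper-right quadrant cannot map to five labels
    rows = []
    for j, cx in enumerate([1.0, 2.0, 3.0, 4.0, 5.0]):
        for i in range(20):
            rows.append((f"p{j}_{i}", cx + rng.normal(0, 0.05), 2.0 + rng.normal(0, 0.05)))
    df = pd.DataFrame(rows, columns=["protein_id", "protein_log2", "mrna_log2"])
    with pytest.raises(ValueError, match="centroid"):
        kmeans_partition(df, seed=0)


def test_positive_correlation_count():
    part = ConcordancePartition(
        groups={
            "up_up": tuple(f"a{i}" for i in range(127)),
            "down_down": tuple(f"b{i}" for i in range(147)),
            "up_down": tuple(f"c{i}" for i in range(78)),
            "down_up": tuple(f"d{i}" for i in range(218)),
            "unchanged": tuple(f"e{i}" for i in range(118)),
        },
        centroids={},
        inertia=0.0,
        seed=0,
    )
    assert part.n_positive == 274
    assert part.n_negative == 296
    assert sum(part.group_sizes().values()) == 688


def _module(mid, members, label="down"):
    return FunctionalModule(mid, frozenset(members), "T", 1e-4, label, 1e-4, 0)


def test_module_expression_mean_and_sd():
    profiles = pd.DataFrame(
        {
            "protein_id": ["A", "B"],
            "protein_log2": [1.0, 2.0],  # linear ratios 2 and 4
            "mrna_log2": [0.0, 0.0],
        }
    )
    out = module_expression_summary([_module("M1", ["A", "B"])], profiles)
    row = out.iloc[0]
    assert row["protein_mean"] == pytest.approx(3.0)
    assert row["protein_sd"] == pytest.approx(np.std([2.0, 4.0], ddof=1))
    assert row["mrna_mean"] == pytest.approx(1.0)


def test_module_without_profiles_omitted():
    profiles = pd.DataFrame(
        {"protein_id": ["A"], "protein_log2": [1.0], "mrna_log2": [0.0]}
    )
    out = module_expression_summary([_module("M1", ["X", "Y"])], profiles)
    assert out.empty


def test_pattern_agreement_study_example():
    a = {f"P{i}": "up" for i in range(33)}
    b = dict(a)
    for i in range(3):
        b[f"P{i}"] = "down"
    result = pattern_agreement(a, b)
    assert result.percentage == 90.91
    assert result.n_agree == 30


def test_pattern_agreement_identical_and_disjoint():
    a = {"A": "up", "B": "down"}
    assert pattern_agreement(a, a).percentage == 100.00
    b = {"A": "down", "B": "up"}
    assert pattern_agreement(a, b).percentage == 0.00


def test_pattern_agreement_empty_intersection_rejected():
    with pytest.raises(ValueError):
        pattern_agreement({"A": "up"}, {"B": "up"})
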