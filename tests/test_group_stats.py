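"""Rank statistics across groups: Kruskal–Wallis, Dunn, BH, composition."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_model_from_truth
from mtscape.group_stats import (
    GroupStatsError,
    bh_adjust,
    category_composition,
    dunn_posthoc,
    kruskal_across,
    property_scan,
)

# --- explicit-formula oracles --------------------------------------------


def kw_oracle(groups):
    """Tie-corrected Kruskal–Wallis H by explicit rank sums."""
    pooled = [v for g in groups for v in g]
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and pooled[order[j]] == pooled[order[i]]:
            j += 1
        avg = (i + 1 + j) / 2.0
        for t in range(i, j):
            ranks[order[t]] = avg
        i = j
    n = len(pooled)
    h = 0.0
    pos = 0
    for g in groups:
        r_sum = sum(ranks[pos : pos + len(g)])
        h += r_sum**2 / len(g)
        pos += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    counts = {}
    for v in pooled:
        counts[v] = counts.get(v, 0) + 1
    tie = sum(c**3 - c for c in counts.values())
    return h / (1.0 - tie / (n**3 - n))


def dunn_oracle(groups_dict):
    """Dunn z for every pair, by explicit mean ranks and tie-corrected SE."""
    names = list(groups_dict)
    pooled = [v for k in names for v in groups_dict[k]]
    ranks = stats.rankdata(pooled)
    mean_rank, size, pos = {}, {}, 0
    for k in names:
        n_k = len(groups_dict[k])
        mean_rank[k] = ranks[pos : pos + n_k].mean()
        size[k] = n_k
        pos += n_k
    n = len(pooled)
    counts = {}
    for v in pooled:
        counts[v] = counts.get(v, 0) + 1
    tie = sum(c**3 - c for c in counts.values())
    unit = n * (n + 1) / 12.0 - tie / (12.0 * (n - 1))
    out = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            se = np.sqrt(unit * (1 / size[a] + 1 / size[b]))
            out[(a, b)] = (mean_rank[a] - mean_rank[b]) / se
    return out


def bh_oracle(p):
    """Step-up BH by explicit sort."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, m * p[i] / rank_from_top)
        adj[i] = min(val, 1.0)
        prev = val
    return adj


# --- Kruskal–Wallis -------------------------------------------------------


def test_kruskal_identical_groups_matches_rank_sum_oracle():
    groups = {"a": np.array([1.0, 2.0, 3.0]), "b": np.array([1.0, 2.0, 3.0])}
    h, p = kruskal_across(groups)
    assert h == pytest.approx(kw_oracle(list(groups.values())), rel=1e-9)
    assert p > 0.9


def test_kruskal_requires_two_nonempty_groups():
    with pytest.raises(GroupStatsError):
        kruskal_across({"a": np.array([1.0, 2.0]), "b": np.array([])})


def test_kruskal_null_calibration():
    """Type-I error at α=0.05 under the null sits in the binomial 99% interval."""
    rng = np.random.default_rng(2024)
    n_sim, n = 1000, 200
    rejections = 0
    for _ in range(n_sim):
        a, b = rng.normal(size=n), rng.normal(size=n)
        _, p = kruskal_across({"a": a, "b": b})
        rejections += p < 0.05
    lo = stats.binom.ppf(0.005, n_sim, 0.05)
    hi = stats.binom.ppf(0.995, n_sim, 0.05)
    assert lo <= rejections <= hi


def test_kruskal_monotone_transform_invariance():
    rng = np.random.default_rng(5)
    groups = {"a": rng.normal(size=30), "b": rng.normal(1.0, 1.0, size=25)}
    h1, p1 = kruskal_across(groups)
    h2, p2 = kruskal_across({k: np.exp(v) for k, v in groups.items()})
    assert h1 == pytest.approx(h2, rel=1e-12)
    assert p1 == pytest.approx(p2, rel=1e-12)


# --- Dunn -----------------------------------------------------------------


def test_dunn_z_matches_explicit_oracle_on_toy_instance():
    groups = {"a": np.array([1.0, 4.0]), "b": np.array([2.0, 2.0]), "c": np.array([5.0, 6.0])}
    table = dunn_posthoc(groups, mode="pairwise")
    oracle = dunn_oracle(groups)
    for _, row in table.iterrows():
        assert row["dunn_z"] == pytest.approx(oracle[(row["group_i"], row["group_j"])], rel=1e-9)


def test_dunn_detects_only_the_shifted_group():
    rng = np.random.default_rng(11)
    groups = {
        "a": rng.normal(0, 1, 50),
        "b": rng.normal(0, 1, 50),
        "c": rng.normal(10.0, 1, 50),  # shifted by 10σ
    }
    table = dunn_posthoc(groups, mode="pairwise")
    involves_c = table["group_j"].eq("c") | table["group_i"].eq("c")
    assert (table.loc[involves_c, "p_adj"] < 0.05).all()
    assert (table.loc[~involves_c, "p_adj"] >= 0.05).all()
    rest = dunn_posthoc(groups, mode="cluster_vs_rest")
    assert set(rest["group_j"]) == {"rest"}
    assert rest.set_index("group_i").loc["c", "p_adj"] < 0.05


def test_dunn_all_identical_values():
    groups = {"a": np.full(4, 2.0), "b": np.full(5, 2.0)}
    table = dunn_posthoc(groups, mode="pairwise")
    assert (table["dunn_z"] == 0.0).all()
    assert (table["p_adj"] == 1.0).all()


# --- BH -------------------------------------------------------------------


def test_bh_single_p_is_identity():
    assert bh_adjust([0.04])[0] == pytest.approx(0.04)


def test_bh_hand_applied_step_up():
    adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])


def test_bh_matches_explicit_oracle_and_properties():
    rng = np.random.default_rng(3)
    for _ in range(25):
        p = rng.uniform(size=rng.integers(1, 12))
        adj = bh_adjust(p)
        assert np.allclose(adj, bh_oracle(list(p)), rtol=1e-9)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)
        # order-consistency: adjusted ranks follow raw ranks
        assert np.all(np.diff(adj[np.argsort(p)]) >= -1e-12)


def test_bh_rejects_out_of_range():
    with pytest.raises(GroupStatsError):
        bh_adjust([0.5, 1.2])


# --- property scan and composition ---------------------------------------


def truth_two_groups(n=40):
    return {f"g{i}": ("A" if i < n // 2 else "B") for i in range(n)}


def test_property_scan_flags_only_shifted_property():
    truth = truth_two_groups(60)
    model = make_model_from_truth(truth)
    rng = np.random.default_rng(21)
    table = pd.DataFrame(
        {
            "len": [rng.normal(30 + (30 if truth[g] == "A" else 0), 1) for g in truth],
            "gravy": rng.normal(size=len(truth)),
        },
        index=pd.Index(list(truth), name="gene_id"),
    )
    results = {r.property: r for r in property_scan(table, model)}
    assert results["len"].kw_p < 0.05
    a_row = results["len"].pairwise.set_index("group_i").loc["A"]
    assert a_row["p_adj"] < 0.05
    assert results["gravy"].kw_p >= 0.05
    assert results["gravy"].pairwise.empty


def test_property_scan_skips_all_missing_property():
    truth = truth_two_groups(20)
    model = make_model_from_truth(truth)
    table = pd.DataFrame(
        {"ok": np.arange(20.0), "empty": np.full(20, np.nan)},
        index=pd.Index(list(truth), name="gene_id"),
    )
    with pytest.warns(UserWarning, match="empty"):
        results = property_scan(table, model)
    assert [r.property for r in results] == ["ok"]


def test_property_scan_deterministic():
    truth = truth_two_groups(30)
    model = make_model_from_truth(truth)
    rng = np.random.default_rng(4)
    table = pd.DataFrame(
        {"a": rng.normal(size=30), "b": rng.normal(size=30)},
        index=pd.Index(list(truth), name="gene_id"),
    )
    r1 = property_scan(table, model)
    r2 = property_scan(table, model)
    assert [(r.property, r.kw_statistic, r.kw_p) for r in r1] == [
        (r.property, r.kw_statistic, r.kw_p) for r in r2
    ]


def test_property_scan_requires_overlap():
    model = make_model_from_truth(truth_two_groups(10))
    table = pd.DataFrame({"a": [1.0]}, index=pd.Index(["other"], name="gene_id"))
    with pytest.raises(GroupStatsError):
        property_scan(table, model)


def test_category_composition_fractions():
    truth = {"g0": "A", "g1": "A", "g2": "A", "g3": "A", "g4": "B"}
    model = make_model_from_truth(truth)
    table = pd.DataFrame(
        {"functional_category": ["enzyme", "enzyme", "enzyme", "MRP", "enzyme"]},
        index=pd.Index(list(truth), name="gene_id"),
    )
    comp = category_composition(table, model)
    a = comp[comp["letter"] == "A"].set_index("category")
    assert a.loc["enzyme", "fraction"] == pytest.approx(0.75)
    assert a.loc["MRP", "fraction"] == pytest.approx(0.25)
    # counting oracle + normalization
    for letter, grp in comp.groupby("letter"):
        assert grp["fraction"].sum() == pytest.approx(1.0, abs=1e-12)
        for _, row in grp.iterrows():
            manual = sum(
                1
                for g, l in truth.items()
                if l == letter and table.loc[g, "functional_category"] == row["category"]
            )
            assert row["count"] == manual
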