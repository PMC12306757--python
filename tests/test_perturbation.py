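"""Group response statistics and the size-matched permutation test."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_model_from_truth
from mtscape.perturbation import (
    PerturbationDataset,
    PerturbationError,
    cluster_stat,
    permutation_test,
    run_validation,
    zscore_across,
)


def dataset(fc: dict, condition="c1"):
    return PerturbationDataset(condition, pd.Series(fc, dtype=float))


def two_group_model():
    return make_model_from_truth({"a": "A", "b": "A", "c": "B", "d": "B", "e": "B", "f": "B"})


def exact_p(pool: dict, members: list, sign_mode="both"):
    """Full-enumeration oracle over all size-matched subsets of the pool."""
    obs = np.mean([abs(pool[g]) for g in members])
    size = len(members)
    hits = total = 0
    for combo in combinations(sorted(pool), size):
        vals = [pool[g] for g in combo]
        if sign_mode == "both":
            stat = np.mean([abs(v) for v in vals])
        else:
            raise NotImplementedError
        total += 1
        hits += stat >= obs - 1e-12
    return hits / total


# --- cluster statistic ----------------------------------------------------


def test_cluster_stat_modes():
    model = two_group_model()
    ds = dataset({"a": 1.0, "b": -3.0, "c": 0.5, "d": -0.5, "e": 0.1, "f": 0.2})
    assert cluster_stat(ds, model, "A", "both") == (2.0, 2)
    assert cluster_stat(ds, model, "A", "positive_only") == (1.0, 1)
    assert cluster_stat(ds, model, "A", "negative_only") == (3.0, 1)


def test_cluster_stat_absent_when_unquantified():
    model = two_group_model()
    ds = dataset({"c": 0.5, "d": 1.0})
    stat, n = cluster_stat(ds, model, "A")
    assert stat is None and n == 0


def test_cluster_stat_unknown_letter():
    with pytest.raises(KeyError):
        cluster_stat(dataset({"a": 1.0}), two_group_model(), "Z")


def test_cluster_stat_sign_flip_invariance_mode_both():
    model = two_group_model()
    fc = {"a": 1.3, "b": -0.4, "c": 2.0, "d": 0.1, "e": -1.0, "f": 0.3}
    flipped = {k: -v for k, v in fc.items()}
    assert cluster_stat(dataset(fc), model, "A") == cluster_stat(dataset(flipped), model, "A")


# --- permutation test -----------------------------------------------------


def test_constant_fold_changes_give_p_one():
    model = two_group_model()
    ds = dataset({g: 1.5 for g in "abcdef"})
    res = permutation_test(ds, model, "A", n_iter=999, seed=1)
    assert res.p == 1.0
    assert res.stat == pytest.approx(1.5)


def test_monte_carlo_converges_to_enumeration_oracle():
    """Monte-Carlo p approaches the exact p over all C(6,2)=15 subsets."""
    fc = {"a": 2.0, "b": 1.4, "c": 0.3, "d": -0.2, "e": 0.8, "f": -1.1}
    model = two_group_model()
    p_exact = exact_p(fc, ["a", "b"])
    errs = []
    for n_iter in (999, 9999, 99_999):
        res = permutation_test(dataset(fc), model, "A", n_iter=n_iter, seed=5)
        errs.append(abs(res.p - p_exact))
    assert errs[-1] <= 0.01
    assert errs[-1] <= errs[0] + 0.005  # error does not grow with iterations


def test_permutation_deterministic_given_seed():
    rng = np.random.default_rng(8)
    fc = {f"g{i}": float(v) for i, v in enumerate(rng.normal(size=12))}
    truth = {f"g{i}": ("A" if i < 4 else "B") for i in range(12)}
    model = make_model_from_truth(truth)
    r1 = permutation_test(dataset(fc), model, "A", n_iter=2999, seed=77)
    r2 = permutation_test(dataset(fc), model, "A", n_iter=2999, seed=77)
    assert r1.p == r2.p


def test_permutation_p_floor_and_validation():
    model = two_group_model()
    ds = dataset({"a": 50.0, "b": 60.0, "c": 0.0, "d": 0.0, "e": 0.0, "f": 0.0})
    res = permutation_test(ds, model, "A", n_iter=999, seed=2)
    assert res.p >= 1.0 / 1000
    with pytest.raises(PerturbationError):
        permutation_test(ds, model, "A", n_iter=0, seed=2)


def test_permutation_requires_two_members():
    model = make_model_from_truth({"a": "A", "c": "B", "d": "B"})
    ds = dataset({"a": 1.0, "c": 0.1, "d": 0.2})
    with pytest.raises(PerturbationError, match="need >= 2"):
        permutation_test(ds, model, "A", n_iter=99, seed=0)


def test_permutation_null_super_uniform():
    """Under a random-group null the rejection rate stays at or below α."""
    rng = np.random.default_rng(31)
    truth = {f"g{i}": ("A" if i < 10 else "B") for i in range(60)}
    model = make_model_from_truth(truth)
    rejections = 0
    n_sim = 200
    for s in range(n_sim):
        fc = pd.Series(rng.normal(size=60), index=list(truth))
        res = permutation_test(
            PerturbationDataset("c", fc), model, "A", n_iter=499, seed=s
        )
        rejections += res.p < 0.05
    hi = stats.binom.ppf(0.995, n_sim, 0.05)
    assert rejections <= hi


def test_power_nondecreasing_in_effect_size():
    truth = {f"g{i}": ("A" if i < 15 else "B") for i in range(90)}
    model = make_model_from_truth(truth)
    rates = []
    for effect in (0.5, 1.0, 2.0):
        rng = np.random.default_rng(100)
        hits = 0
        for s in range(40):
            fc = pd.Series(
                [rng.normal(effect if truth[g] == "A" else 0.0, 1.0) for g in truth],
                index=list(truth),
            )
            res = permutation_test(
                PerturbationDataset("c", fc), model, "A", n_iter=999, seed=s
            )
            hits += res.p < 0.05
        rates.append(hits / 40)
    assert rates[0] <= rates[1] + 0.05 <= rates[2] + 0.10
    assert rates[2] > rates[0]


# --- z-scores -------------------------------------------------------------


def make_results(stats_by_letter, condition="c1", mode="both"):
    from mtscape.perturbation import PerturbationResult

    return [
        PerturbationResult(condition, l, mode, 5, stat=s) for l, s in stats_by_letter.items()
    ]


def test_zscore_closed_form():
    results = zscore_across(make_results({"A": 1.0, "B": 2.0, "C": 3.0}))
    assert [r.z for r in results] == pytest.approx([-1.0, 0.0, 1.0])


def test_zscore_normalization_and_shift_invariance():
    rng = np.random.default_rng(9)
    base = {l: float(v) for l, v in zip("ABCDE", rng.uniform(0.2, 3.0, 5))}
    z1 = np.array([r.z for r in zscore_across(make_results(base))])
    assert z1.mean() == pytest.approx(0.0, abs=1e-12)
    assert z1.std(ddof=1) == pytest.approx(1.0, abs=1e-12)
    shifted = {l: v + 7.0 for l, v in base.items()}
    z2 = np.array([r.z for r in zscore_across(make_results(shifted))])
    assert np.allclose(z1, z2, atol=1e-12)


def test_zscore_needs_two_present():
    with pytest.raises(PerturbationError):
        zscore_across(make_results({"A": 1.0}))


# --- full validation ------------------------------------------------------


def test_run_validation_flags_injected_negative_effect():
    rng = np.random.default_rng(13)
    truth = {f"g{i}": "ABC"[i % 3] for i in range(90)}
    model = make_model_from_truth(truth)
    fc = pd.Series(
        [rng.normal(-2.0 if truth[g] == "A" else 0.0, 0.3) for g in truth],
        index=list(truth),
    )
    table = run_validation([PerturbationDataset("mut1", fc)], model, n_iter=4999, seed=3)
    sig = table[table["significant"]]
    assert set(sig["letter"]) == {"A"}
    assert {"both", "negative_only"} <= set(sig["sign_mode"])
    # z present for non-absent cells
    assert table.loc[~table["absent"], "z"].notna().all()


def test_run_validation_disjoint_dataset_all_absent():
    model = two_group_model()
    ds = dataset({"x1": 1.0, "x2": -1.0})
    table = run_validation([ds], model, n_iter=99, seed=0)
    assert table["absent"].all()


def test_run_validation_deterministic():
    rng = np.random.default_rng(14)
    truth = {f"g{i}": ("A" if i < 8 else "B") for i in range(24)}
    model = make_model_from_truth(truth)
    fc = pd.Series(rng.normal(size=24), index=list(truth))
    t1 = run_validation([PerturbationDataset("c", fc)], model, n_iter=999, seed=5)
    t2 = run_validation([PerturbationDataset("c", fc)], model, n_iter=999, seed=5)
    pd.testing.assert_frame_equal(t1, t2)
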