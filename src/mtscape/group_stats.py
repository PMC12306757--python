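"""Group-wise statistics on protein properties.

Each numeric property (gravy, abundance, length, …) is compared across
presequence groups with the Kruskal–Wallis test; where the omnibus test
is significant, Dunn's post hoc test locates the groups that deviate,
either pairwise or each group against the union of the others
("cluster vs rest"), with Benjamini–Hochberg adjustment within each
property.  All tests are rank-based, so monotone transforms of the
values do not change the results.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from mtscape.landscape import ClusterModel

PROPERTY_COLUMNS = [
    "gravy_score",
    "abundance_median",
    "aromaticity_score",
    "codon_bias",
    "protein_length",
    "molecular_weight",
    "aliphatic_index",
    "instability_index",
    "protein_half_life",
    "melting_temperature",
]


class GroupStatsError(ValueError):
    pass


@dataclass
class GroupTestResult:
    """Omnibus and post hoc results for one property."""

    property: str
    kw_statistic: float
    kw_p: float
    pairwise: pd.DataFrame  # columns: group_i, group_j, dunn_z, p_raw, p_adj


def kruskal_across(values_by_cluster: dict[str, np.ndarray]) -> tuple[float, float]:
    """Kruskal–Wallis H across groups (tie-corrected, chi² p-value)."""
    groups = [np.asarray(v, dtype=float) for v in values_by_cluster.values() if len(v) > 0]
    if len(groups) < 2:
        raise GroupStatsError("Kruskal–Wallis needs at least 2 non-empty groups")
    if sum(len(g) for g in groups) < 3:
        raise GroupStatsError("Kruskal–Wallis needs total n >= 3")
    try:
        h, p = stats.kruskal(*groups)
    except ValueError as exc:
        # all values identical across all groups: H = 0 by convention
        if "identical" in str(exc):
            return 0.0, 1.0
        raise
    return float(h), float(p)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise GroupStatsError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _tie_term(all_values: np.ndarray) -> float:
    """Σ(t³−t) over tied groups, used in Dunn's tie-corrected variance."""
    _, counts = np.unique(all_values, return_counts=True)
    t = counts[counts > 1].astype(float)
    return float(np.sum(t**3 - t))


def dunn_posthoc(
    values_by_cluster: dict[str, np.ndarray], mode: str = "cluster_vs_rest"
) -> pd.DataFrame:
    """Dunn's post hoc z tests on pooled ranks with tie correction.

    mode="pairwise" compares every pair of groups; "cluster_vs_rest"
    compares each group against the union of all other groups (the
    reading of "differs from the overall distribution").  The z
    statistic for groups i, j is

        z = (R̄_i − R̄_j) / sqrt[(N(N+1)/12 − T/(12(N−1))) (1/n_i + 1/n_j)]

    with N the pooled size and T = Σ(t³−t) over tied values.  Raw p is
    two-sided normal; ``p_adj`` is BH-adjusted across the table.
    """
    names = [k for k, v in values_by_cluster.items() if len(v) > 0]
    if len(names) < 2:
        raise GroupStatsError("Dunn's test needs at least 2 non-empty groups")
    if mode not in ("pairwise", "cluster_vs_rest"):
        raise GroupStatsError(f"unknown mode {mode!r}")
    vals = {k: np.asarray(values_by_cluster[k], dtype=float) for k in names}
    pooled = np.concatenate([vals[k] for k in names])
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_rank: dict[str, float] = {}
    sizes: dict[str, int] = {}
    pos = 0
    for k in names:
        n_k = len(vals[k])
        mean_rank[k] = float(ranks[pos : pos + n_k].mean())
        sizes[k] = n_k
        pos += n_k
    tie = _tie_term(pooled)
    var_unit = n_total * (n_total + 1) / 12.0 - tie / (12.0 * (n_total - 1))
    rows = []
    if mode == "pairwise":
        comparisons = [
            (names[i], names[j]) for i in range(len(names)) for j in range(i + 1, len(names))
        ]
        for a, b in comparisons:
            se = np.sqrt(var_unit * (1.0 / sizes[a] + 1.0 / sizes[b]))
            z = 0.0 if se == 0 else (mean_rank[a] - mean_rank[b]) / se
            rows.append({"group_i": a, "group_j": b, "dunn_z": z})
    else:
        for a in names:
            n_rest = n_total - sizes[a]
            rest_mean = (ranks.sum() - mean_rank[a] * sizes[a]) / n_rest
            se = np.sqrt(var_unit * (1.0 / sizes[a] + 1.0 / n_rest))
            z = 0.0 if se == 0 else (mean_rank[a] - rest_mean) / se
            rows.append({"group_i": a, "group_j": "rest", "dunn_z": z})
    df = pd.DataFrame(rows)
    df["p_raw"] = 2.0 * stats.norm.sf(np.abs(df["dunn_z"]))
    df["p_adj"] = bh_adjust(df["p_raw"].to_numpy())
    return df


def _values_by_letter(
    series: pd.Series, assignments: pd.Series
) -> dict[str, np.ndarray]:
    joined = pd.DataFrame({"value": series}).join(assignments, how="inner").dropna()
    return {
        letter: grp["value"].to_numpy()
        for letter, grp in joined.groupby("letter", sort=True)
    }


def property_scan(
    properties: pd.DataFrame,
    model: ClusterModel,
    alpha: float = 0.05,
    mode: str = "cluster_vs_rest",
) -> list[GroupTestResult]:
    """KW omnibus per numeric property; Dunn post hoc where kw_p < alpha.

    ``properties`` is indexed by gene_id; non-numeric columns (e.g.
    functional_category) are ignored.  Missing values are dropped per
    property, never imputed.
    """
    assignments = model.assignments()
    overlap = properties.index.intersection(assignments.index)
    if len(overlap) == 0:
        raise GroupStatsError("no overlap between property table and clustered gene_ids")
    if len(overlap) < 0.5 * len(assignments):
        warnings.warn(
            f"only {len(overlap)}/{len(assignments)} clustered proteins have properties",
            stacklevel=2,
        )
    results = []
    for col in properties.columns:
        if not pd.api.types.is_numeric_dtype(properties[col]):
            continue
        series = properties[col].dropna()
        if series.empty:
            warnings.warn(f"property {col!r} has no values; skipped", stacklevel=2)
            continue
        by_letter = _values_by_letter(series, assignments)
        by_letter = {k: v for k, v in by_letter.items() if len(v) > 0}
        if len(by_letter) < 2:
            warnings.warn(f"property {col!r}: fewer than 2 groups with data; skipped", stacklevel=2)
            continue
        h, p = kruskal_across(by_letter)
        if p < alpha:
            pairwise = dunn_posthoc(by_letter, mode=mode)
        else:
            pairwise = pd.DataFrame(columns=["group_i", "group_j", "dunn_z", "p_raw", "p_adj"])
        results.append(GroupTestResult(col, h, p, pairwise))
    return results


def category_composition(properties: pd.DataFrame, model: ClusterModel) -> pd.DataFrame:
    """Functional-category counts and within-group fractions per letter group.

    Categories absent from a group are reported with count 0; a group
    with no annotated members yields all-zero rows and a warning.
    """
    if "functional_category" not in properties.columns:
        raise GroupStatsError("property table lacks a functional_category column")
    assignments = model.assignments()
    cats = sorted(properties["functional_category"].dropna().unique())
    joined = pd.DataFrame({"category": properties["functional_category"]}).join(
        assignments, how="inner"
    ).dropna()
    rows = []
    for letter in sorted(set(assignments)):
        sub = joined[joined["letter"] == letter]
        total = len(sub)
        if total == 0:
            warnings.warn(f"group {letter}: no annotated members", stacklevel=2)
        for cat in cats:
            count = int((sub["category"] == cat).sum())
            rows.append(
                {
                    "letter": letter,
                    "category": cat,
                    "count": count,
                    "fraction": count / total if total else 0.0,
                }
            )
    return pd.DataFrame(rows)
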