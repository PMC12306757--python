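"""Group responses in perturbation proteomics, scored by permutation.

For each perturbation condition (a table of per-protein log2 fold
changes relative to control) and each presequence group, the statistic
is the mean absolute log2 fold change over the group's quantified
members (optionally restricted to positive or negative changes).  Its
significance is assessed against size-matched random protein groupings
drawn without replacement from all clustered-and-quantified proteins
(99,999 iterations by default), with the +1-corrected one-sided
Monte-Carlo p-value.  For cross-condition comparability the statistics
are z-scored across groups within each condition.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from mtscape.landscape import ClusterModel

SIGN_MODES = ("both", "positive_only", "negative_only")


class PerturbationError(ValueError):
    pass


@dataclass
class PerturbationDataset:
    """One condition's log2 fold changes relative to control."""

    condition_id: str
    fold_changes: pd.Series  # index gene_id, finite floats
    source: str = "unknown"

    def __post_init__(self) -> None:
        fc = pd.Series(self.fold_changes, dtype=float)
        if fc.index.has_duplicates:
            raise PerturbationError(f"{self.condition_id}: duplicate gene_ids")
        if not np.all(np.isfinite(fc.to_numpy())):
            raise PerturbationError(f"{self.condition_id}: non-finite fold changes")
        self.fold_changes = fc


@dataclass
class PerturbationResult:
    """Per-(condition, group, sign-mode) permutation outcome.

    ``absent`` flags cells with no (or too few) quantified members;
    such cells carry no statistic.
    """

    condition_id: str
    letter: str
    sign_mode: str
    n_used: int
    stat: Optional[float] = None
    p: Optional[float] = None
    z: Optional[float] = None
    absent: bool = False
    reason: str = ""


def _signed_values(fc: np.ndarray, sign_mode: str) -> np.ndarray:
    if sign_mode == "both":
        return np.abs(fc)
    if sign_mode == "positive_only":
        return fc[fc > 0]
    if sign_mode == "negative_only":
        return np.abs(fc[fc < 0])
    raise PerturbationError(f"unknown sign_mode {sign_mode!r}")


def cluster_stat(
    dataset: PerturbationDataset,
    model: ClusterModel,
    letter: str,
    sign_mode: str = "both",
) -> tuple[Optional[float], int]:
    """Mean |log2FC| (per sign mode) over the group's quantified members.

    Returns (stat, n_used); stat is None when no member contributes
    (absent cell).  n_used counts the fold changes that entered the
    mean.
    """
    members = model.members(letter)  # KeyError for unknown letters
    fc = dataset.fold_changes.reindex(members).dropna().to_numpy()
    vals = _signed_values(fc, sign_mode)
    if len(vals) == 0:
        return None, 0
    return float(vals.mean()), int(len(vals))


def _null_stats(
    pool: np.ndarray, size: int, n_iter: int, rng: np.random.Generator, sign_mode: str
) -> np.ndarray:
    """Statistics of n_iter random size-matched subsets of the pool."""
    idx = np.argsort(rng.random((n_iter, len(pool))), axis=1)[:, :size]
    draws = pool[idx]  # (n_iter, size)
    if sign_mode == "both":
        return np.abs(draws).mean(axis=1)
    if sign_mode == "positive_only":
        mask = draws > 0
    else:
        mask = draws < 0
    cnt = mask.sum(axis=1)
    with np.errstate(invalid="ignore"):
        out = np.where(cnt > 0, np.abs(np.where(mask, draws, 0.0)).sum(axis=1) / cnt, np.nan)
    return out


def permutation_test(
    dataset: PerturbationDataset,
    model: ClusterModel,
    letter: str,
    n_iter: int = 99_999,
    seed: int = 0,
    sign_mode: str = "both",
    two_sided: bool = False,
) -> PerturbationResult:
    """Size-matched permutation test for one group in one condition.

    Null statistics come from ``n_iter`` subsets of size n_used drawn
    without replacement from all clustered proteins quantified in the
    dataset.  One-sided p = (1 + #{null ≥ observed}) / (n_iter + 1);
    the +1 correction keeps p valid and strictly positive.  Null draws
    whose statistic is undefined under a signed mode (no value of the
    required sign) are treated as not exceeding the observed statistic.
    """
    if n_iter < 1:
        raise PerturbationError("n_iter must be >= 1")
    stat, n_used = cluster_stat(dataset, model, letter, sign_mode)
    if stat is None:
        return PerturbationResult(
            dataset.condition_id, letter, sign_mode, 0, absent=True, reason="no quantified members"
        )
    if n_used < 2:
        raise PerturbationError(
            f"{dataset.condition_id}/{letter}: only {n_used} quantified member(s); need >= 2"
        )
    clustered = pd.Index(model.gene_ids)
    pool = dataset.fold_changes.reindex(clustered).dropna().to_numpy()
    rng = np.random.default_rng(seed)
    null = _null_stats(pool, n_used, n_iter, rng, sign_mode)
    valid = np.isfinite(null)
    if two_sided:
        center = np.nanmean(null)
        exceed = np.sum(np.abs(null[valid] - center) >= abs(stat - center))
    else:
        exceed = np.sum(null[valid] >= stat)
    p = (1.0 + float(exceed)) / (n_iter + 1.0)
    return PerturbationResult(dataset.condition_id, letter, sign_mode, n_used, stat=stat, p=p)


def zscore_across(results: Iterable[PerturbationResult]) -> list[PerturbationResult]:
    """Standardize statistics across groups within one condition.

    z = (stat − mean over groups) / sample sd over groups; absent cells
    are excluded and stay absent.  All results must share one condition
    and sign mode.
    """
    results = list(results)
    keys = {(r.condition_id, r.sign_mode) for r in results}
    if len(keys) != 1:
        raise PerturbationError("zscore_across expects one condition and one sign mode")
    present = [r for r in results if not r.absent and r.stat is not None]
    if len(present) < 2:
        raise PerturbationError("need >= 2 non-absent groups to z-score")
    stats_ = np.array([r.stat for r in present])
    mu = stats_.mean()
    sd = stats_.std(ddof=1)
    for r in present:
        r.z = 0.0 if sd == 0 else float((r.stat - mu) / sd)
    return results


def run_validation(
    datasets: Iterable[PerturbationDataset],
    model: ClusterModel,
    n_iter: int = 99_999,
    alpha: float = 0.05,
    seed: int = 0,
    sign_modes: tuple[str, ...] = SIGN_MODES,
) -> pd.DataFrame:
    """Full condition × group × sign-mode permutation scan.

    Returns a long table with columns condition_id, letter, sign_mode,
    n_used, stat, p, z, significant, absent, reason.  Per-cell
    failures (too few members) are recorded as absent rows, never
    raised.  Seeds are derived deterministically per cell from ``seed``.
    """
    letters = sorted(model.letters.values())
    rows: list[PerturbationResult] = []
    for d_i, dataset in enumerate(datasets):
        for mode in sign_modes:
            mode_results = []
            for l_i, letter in enumerate(letters):
                cell_seed = int(
                    np.random.SeedSequence([seed, d_i, SIGN_MODES.index(mode), l_i])
                    .generate_state(1)[0] % (2**31)
                )
                try:
                    res = permutation_test(
                        dataset, model, letter, n_iter=n_iter, seed=cell_seed, sign_mode=mode
                    )
                except PerturbationError as exc:
                    res = PerturbationResult(
                        dataset.condition_id, letter, mode, 0, absent=True, reason=str(exc)
                    )
                mode_results.append(res)
            present = [r for r in mode_results if not r.absent]
            if len(present) >= 2:
                zscore_across(mode_results)
            rows.extend(mode_results)
    df = pd.DataFrame(
        [
            {
                "condition_id": r.condition_id,
                "letter": r.letter,
                "sign_mode": r.sign_mode,
                "n_used": r.n_used,
                "stat": r.stat,
                "p": r.p,
                "z": r.z,
                "significant": (r.p is not None and r.p < alpha),
                "absent": r.absent,
                "reason": r.reason,
            }
            for r in rows
        ]
    )
    return df


def load_datasets(path: str | Path, layout: str = "long") -> list[PerturbationDataset]:
    """Read perturbation datasets from TSV.

    layout="long": columns condition_id, gene_id, log2fc.
    layout="wide": gene_id column plus one column per condition.
    """
    df = pd.read_csv(path, sep="\t")
    out = []
    if layout == "long":
        for cond, grp in df.groupby("condition_id", sort=True):
            fc = pd.Series(grp["log2fc"].to_numpy(), index=grp["gene_id"].astype(str))
            out.append(PerturbationDataset(str(cond), fc, source=str(path)))
    elif layout == "wide":
        df = df.set_index("gene_id")
        for cond in df.columns:
            fc = df[cond].dropna()
            out.append(PerturbationDataset(str(cond), fc, source=str(path)))
    else:
        raise PerturbationError(f"unknown layout {layout!r}")
    return out


def write_datasets(datasets: Iterable[PerturbationDataset], path: str | Path) -> None:
    """Write datasets as long TSV (condition_id, gene_id, log2fc)."""
    frames = [
        pd.DataFrame(
            {
                "condition_id": d.condition_id,
                "gene_id": d.fold_changes.index,
                "log2fc": d.fold_changes.to_numpy(),
            }
        )
        for d in datasets
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
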