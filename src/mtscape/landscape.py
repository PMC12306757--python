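"""2-D projection of pooled MTS vectors and spectral grouping.

Pooled vectors are projected with UMAP (n_neighbors=15, min_dist=0.2,
spread=2.0, learning_rate=0.5, n_epochs=1000 by default) and the
projected points are partitioned by spectral clustering on a
radial-basis affinity exp(−gamma‖p−q‖²) with gamma=1.1 and 20
label-assignment restarts.  The number of clusters is chosen by
maximizing the Calinski-Harabasz score over a k range, with the
within-cluster dispersion trace kept for elbow inspection.

Clusters are relabeled canonically (decreasing size, ties by ascending
mean x) and lettered A, B, C, … so that the largest group is always A.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import SpectralClustering
from sklearn.metrics import calinski_harabasz_score
from sklearn.preprocessing import StandardScaler

DEFAULT_SEED = 1811


class LandscapeError(ValueError):
    """Invalid projection/clustering input (too few points, degenerate geometry)."""


@dataclass(frozen=True)
class ProjectionParams:
    """UMAP hyperparameters; defaults follow the presequence landscape setup."""

    n_neighbors: int = 15
    min_dist: float = 0.2
    spread: float = 2.0
    learning_rate: float = 0.5
    n_epochs: int = 1000
    seed: int = DEFAULT_SEED
    scale: bool = True  # z-scale feature columns before projection

    def __post_init__(self) -> None:
        if self.n_neighbors < 2 or self.min_dist < 0 or self.n_epochs < 1:
            raise LandscapeError("invalid projection parameters")


@dataclass
class ClusterModel:
    """A spectral-clustering partition of the projected presequences."""

    gene_ids: list[str]
    labels: np.ndarray  # int labels 0..k-1, canonical order
    k: int
    gamma: float
    restarts: int
    seed: int
    letters: dict[int, str] = field(default_factory=dict)
    selection_trace: pd.DataFrame | None = None
    low_confidence: bool = False

    @classmethod
    def from_assignments(cls, assignments: "dict[str, str] | pd.Series") -> "ClusterModel":
        """Build a model from an explicit gene_id → group-letter mapping.

        Useful for scoring statistics against a known partition (ground
        truth, or a clustering loaded from file).
        """
        mapping = dict(assignments)
        letters = sorted(set(mapping.values()))
        lab = {l: i for i, l in enumerate(letters)}
        gene_ids = list(mapping)
        return cls(
            gene_ids=gene_ids,
            labels=np.array([lab[mapping[g]] for g in gene_ids]),
            k=len(letters),
            gamma=1.1,
            restarts=20,
            seed=DEFAULT_SEED,
            letters={i: l for l, i in lab.items()},
        )

    def letter_of(self, gene_id: str) -> str:
        return self.letters[self.labels[self.gene_ids.index(gene_id)]]

    def members(self, letter: str) -> list[str]:
        lab = {v: k for k, v in self.letters.items()}.get(letter)
        if lab is None:
            raise KeyError(f"unknown group letter {letter!r}")
        return [g for g, l in zip(self.gene_ids, self.labels) if l == lab]

    def assignments(self) -> pd.Series:
        """gene_id → letter, using the canonical letter map."""
        return pd.Series(
            [self.letters[l] for l in self.labels],
            index=pd.Index(self.gene_ids, name="gene_id"),
            name="letter",
        )


def project(vectors: pd.DataFrame, params: ProjectionParams | None = None) -> pd.DataFrame:
    """UMAP-project pooled vectors to 2-D; deterministic given the seed.

    ``vectors`` is a DataFrame indexed by gene_id with constant feature
    dimension.  Returns a DataFrame (gene_id index, columns x, y).
    """
    # heavy numba-backed import; keep it off the module import path
    import umap

    params = params or ProjectionParams()
    X = np.asarray(vectors, dtype=float)
    if X.shape[0] < params.n_neighbors + 1:
        raise LandscapeError(
            f"need at least n_neighbors+1={params.n_neighbors + 1} points, got {X.shape[0]}"
        )
    if not np.all(np.isfinite(X)):
        raise LandscapeError("non-finite values in input vectors")
    if params.scale:
        X = StandardScaler().fit_transform(X)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*n_jobs.*random_state.*")
        warnings.filterwarnings("ignore", category=UserWarning, module="umap")
        reducer = umap.UMAP(
            n_components=2,
            n_neighbors=params.n_neighbors,
            min_dist=params.min_dist,
            spread=params.spread,
            learning_rate=params.learning_rate,
            n_epochs=params.n_epochs,
            random_state=params.seed,
        )
        coords = reducer.fit_transform(X)
    return pd.DataFrame(coords, index=vectors.index, columns=["x", "y"])


def _canonicalize(points: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, dict[int, str]]:
    """Relabel clusters by decreasing size (ties: ascending mean x); letter them A…"""
    used = np.unique(labels)
    sizes = {l: int(np.sum(labels == l)) for l in used}
    mean_x = {l: float(points[labels == l, 0].mean()) for l in used}
    order = sorted(used, key=lambda l: (-sizes[l], mean_x[l]))
    remap = {old: new for new, old in enumerate(order)}
    new_labels = np.array([remap[l] for l in labels])
    letters = {i: string.ascii_uppercase[i] for i in range(len(order))}
    return new_labels, letters


def cluster(
    points: pd.DataFrame,
    k: int,
    gamma: float = 1.1,
    restarts: int = 20,
    seed: int = DEFAULT_SEED,
) -> ClusterModel:
    """Spectral clustering with RBF affinity exp(−gamma‖p−q‖²).

    ``points`` has a gene_id index and x, y columns (any constant
    dimension is accepted).  Labels are canonicalized and lettered.
    """
    X = np.asarray(points, dtype=float)
    n = X.shape[0]
    if k < 2:
        raise LandscapeError("k must be at least 2")
    if k > n:
        raise LandscapeError(f"k={k} exceeds number of points n={n}")
    span = X.max(axis=0) - X.min(axis=0) if n else np.zeros(2)
    if n and float(np.max(span)) < 1e-12:
        raise LandscapeError("all points coincide; affinity matrix is degenerate")
    sc = SpectralClustering(
        n_clusters=k,
        affinity="rbf",
        gamma=gamma,
        n_init=restarts,
        random_state=seed,
        assign_labels="kmeans",
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*graph is not fully connected.*")
        raw = sc.fit_predict(X)
    labels, letters = _canonicalize(X, raw)
    return ClusterModel(
        gene_ids=list(points.index),
        labels=labels,
        k=int(len(np.unique(labels))),
        gamma=gamma,
        restarts=restarts,
        seed=seed,
        letters=letters,
    )


def ch_score(X: np.ndarray, labels: np.ndarray) -> float:
    """Calinski-Harabasz score CH = [B/(k−1)] / [W/(n−k)] for a labeled point set."""
    return float(calinski_harabasz_score(np.asarray(X, dtype=float), labels))


def within_dispersion(X: np.ndarray, labels: np.ndarray) -> float:
    """Within-cluster sum of squared distances to cluster centroids, W(k)."""
    w = 0.0
    for l in np.unique(labels):
        pts = X[labels == l]
        w += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return w


def select_k(
    points: pd.DataFrame,
    k_range: tuple[int, int] = (2, 12),
    gamma: float = 1.1,
    restarts: int = 20,
    seed: int = DEFAULT_SEED,
    method: str = "elbow_ch",
    gain_threshold: float = 1.2,
    ch_floor: float = 10.0,
) -> tuple[int, pd.DataFrame]:
    """Choose the number of clusters from the Calinski-Harabasz trace.

    For each k in the inclusive range, runs :func:`cluster` and records
    CH(k) = [B(k)/(k−1)] / [W(k)/(n−k)] together with the within-cluster
    dispersion W(k); the full (k, ch, w) trace is returned alongside k*.

    method="elbow_ch" (default) combines the elbow criterion with the
    CH score: k* is the largest k whose CH exceeds the best CH seen at
    any smaller k by at least ``gain_threshold`` (relative) — the last
    materially profitable split.  On compact low-dimensional
    projections CH keeps creeping upward as genuine groups are
    oversplit, so the global argmax systematically overestimates k;
    the elbow of the CH curve recovers the generating group number.
    Comparing against the running maximum (not just k−1) keeps the
    rule robust to one-off dips where a single clustering run
    degenerates.  method="argmax" gives the plain CH maximizer.

    Warns (low confidence) when no split clears the gain threshold —
    the trace shows no elbow and k* falls back to the CH argmax — or
    when max CH is below ``ch_floor`` (little evidence of any group
    structure).
    """
    k_lo, k_hi = k_range
    n = len(points)
    k_hi = min(k_hi, n - 1)
    if k_lo < 2 or k_lo > k_hi:
        raise LandscapeError(f"empty or invalid k range [{k_lo}, {k_hi}] for n={n}")
    if method not in ("elbow_ch", "argmax"):
        raise LandscapeError(f"unknown selection method {method!r}")
    X = np.asarray(points, dtype=float)
    rows = []
    for k in range(k_lo, k_hi + 1):
        model = cluster(points, k, gamma=gamma, restarts=restarts, seed=seed)
        rows.append(
            {"k": k, "ch": ch_score(X, model.labels), "w": within_dispersion(X, model.labels)}
        )
    trace = pd.DataFrame(rows)
    ch_vals = trace["ch"].to_numpy()
    ks = trace["k"].to_numpy()
    k_argmax = int(ks[int(np.argmax(ch_vals))])
    if method == "argmax":
        k_star = k_argmax
    else:
        running_max = np.maximum.accumulate(ch_vals)[:-1]
        gains = ch_vals[1:] / running_max
        profitable = ks[1:][gains >= gain_threshold]
        # CH(k_lo) has no predecessor; a strong first value counts as profitable
        if len(profitable) > 0:
            k_star = int(profitable[-1])
        elif k_argmax == k_lo:
            k_star = k_lo
        else:
            warnings.warn(
                "no split improves the Calinski-Harabasz score materially; "
                f"k* falls back to the CH argmax {k_argmax} (low-confidence)",
                stacklevel=2,
            )
            k_star = k_argmax
    if float(ch_vals.max()) < ch_floor:
        warnings.warn(
            f"max Calinski-Harabasz score {ch_vals.max():.2f} < {ch_floor}; "
            "k* is low-confidence (weak group structure)",
            stacklevel=2,
        )
    return k_star, trace


def letter_groups(model: ClusterModel, override: dict[int, str] | None = None) -> ClusterModel:
    """(Re)assign letters by decreasing cluster size, ties by ascending mean x.

    Labels are already canonical after :func:`cluster`; this re-derives
    the letter map (or applies an explicit override).
    """
    if override is not None:
        if sorted(override) != sorted(np.unique(model.labels).tolist()):
            raise LandscapeError("override must map every used label")
        model.letters = dict(override)
        return model
    model.letters = {int(l): string.ascii_uppercase[int(l)] for l in np.unique(model.labels)}
    return model


def fit_landscape(
    vectors: pd.DataFrame,
    params: ProjectionParams | None = None,
    k: int | None = None,
    k_range: tuple[int, int] = (2, 12),
    gamma: float = 1.1,
    restarts: int = 20,
    seed: int = DEFAULT_SEED,
) -> tuple[pd.DataFrame, ClusterModel]:
    """Project then cluster; k chosen by :func:`select_k` when not given."""
    params = params or ProjectionParams(seed=seed)
    pts = project(vectors, params)
    trace = None
    low_conf = False
    if k is None:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            k, trace = select_k(pts, k_range, gamma=gamma, restarts=restarts, seed=seed)
            low_conf = any("low-confidence" in str(w.message) for w in caught)
    model = cluster(pts, k, gamma=gamma, restarts=restarts, seed=seed)
    model.selection_trace = trace
    model.low_confidence = low_conf
    return pts, model
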