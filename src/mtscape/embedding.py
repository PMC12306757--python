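"""MTS–carrier fusions and per-residue embedding with mean pooling.

Each presequence is fused to a carrier protein (by default mouse DHFR)
in place of the carrier's initiator methionine, mimicking the classic
MTS-DHFR import constructs.  A pluggable embedder turns the fusion into
an L×d matrix of per-residue features; the carrier rows are discarded
and the MTS rows mean-pooled into one fixed-length vector per
presequence.

The default embedder is a deterministic physicochemical surrogate whose
feature axes are the ones that define a matrix-targeting presequence:
hydrophobicity, formal charge, hydroxylated residues, and the windowed
hydrophobic moment of an idealized helix (100° per residue).  Any
callable mapping a sequence to an L×d matrix can be plugged in instead
(e.g. an adapter around a protein language model).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional

import numpy as np
import pandas as pd
from Bio import SeqIO

from mtscape.catalog import Catalog, PresequenceRecord, VALID_RESIDUES

#: Mouse dihydrofolate reductase (DHFR), the cytosolic carrier fused
#: downstream of each presequence.
DHFR_MOUSE = (
    "MVRPLNCIVAVSQNMGIGKNGDLPWPPLRNEFKYFQRMTTTSSVEGKQNLVIMGRKTWFSIPEKNRPLKDRINIVLSRELKEPPRGAHFLAKSLDDALRLIEQPELASKVDMVWIVGGSSVYQEAMNQPGHLRLFVTRIMQEFESDTFFPEIDLGKYKLLPEYPGVLSEVQEEKGIKYKFEVYEKKD"
)

#: Kyte–Doolittle hydrophobicity scale.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: Formal charge at physiological pH; His treated as neutral by default.
FORMAL_CHARGE = {aa: 0.0 for aa in KYTE_DOOLITTLE}
FORMAL_CHARGE.update({"K": 1.0, "R": 1.0, "D": -1.0, "E": -1.0})

HYDROXYLATED = frozenset("STY")

#: helical rotation per residue, in radians (100 degrees)
HELIX_DELTA = 100.0 * np.pi / 180.0

SURROGATE_FEATURES = [
    "kd_hydrophobicity",
    "formal_charge",
    "hydroxyl",
    "window_mean_hydrophobicity",
    "window_hydrophobic_moment",
    "window_net_charge",
]


class EmbeddingError(ValueError):
    """Embedder contract violation or invalid fusion input."""


@dataclass(frozen=True)
class EngineeredProtein:
    """An MTS fused N-terminally to a carrier, with the MTS span marked.

    ``full_sequence[mts_start:mts_end]`` is the presequence; the rest is
    the carrier minus its initiator methionine.
    """

    gene_id: str
    full_sequence: str
    mts_start: int
    mts_end: int
    carrier_id: str

    @property
    def mts_span(self) -> tuple[int, int]:
        return (self.mts_start, self.mts_end)

    @property
    def mts_sequence(self) -> str:
        return self.full_sequence[self.mts_start : self.mts_end]


@dataclass
class ResidueEmbedding:
    """Per-residue feature matrix (L × d) for one engineered protein."""

    gene_id: str
    matrix: np.ndarray
    embedder_id: str

    @property
    def d(self) -> int:
        return self.matrix.shape[1]


@dataclass
class EmbeddedMTS:
    """Mean-pooled feature vector for one presequence."""

    gene_id: str
    vector: np.ndarray
    embedder_id: str


def build_fusion(
    mts: PresequenceRecord, carrier: str, carrier_id: str = "DHFR_mouse"
) -> EngineeredProtein:
    """Replace the carrier's initiator Met with the presequence.

    full_sequence = MTS + carrier[1:]; the MTS occupies the half-open
    span [0, len(MTS)).
    """
    if len(mts.sequence) < 2:
        raise EmbeddingError(f"{mts.gene_id}: MTS shorter than 2 residues cannot be fused")
    if not carrier or carrier[0] != "M":
        raise EmbeddingError(f"carrier {carrier_id!r} does not start with methionine")
    full = mts.sequence + carrier[1:]
    return EngineeredProtein(
        gene_id=mts.gene_id,
        full_sequence=full,
        mts_start=0,
        mts_end=len(mts.sequence),
        carrier_id=carrier_id,
    )


def embed_residues(
    protein: EngineeredProtein,
    embedder: Callable[[str], np.ndarray],
    embedder_id: str = "custom",
) -> ResidueEmbedding:
    """Run an embedder over the full fusion and validate its contract.

    The embedder must return a finite real matrix with one row per
    residue of ``protein.full_sequence``.
    """
    matrix = np.asarray(embedder(protein.full_sequence), dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != len(protein.full_sequence):
        raise EmbeddingError(
            f"{protein.gene_id}: embedder returned shape {matrix.shape}, "
            f"expected ({len(protein.full_sequence)}, d)"
        )
    if not np.all(np.isfinite(matrix)):
        raise EmbeddingError(f"{protein.gene_id}: embedder returned non-finite entries")
    return ResidueEmbedding(protein.gene_id, matrix, embedder_id)


def pool_mts(embedding: ResidueEmbedding, span: tuple[int, int]) -> EmbeddedMTS:
    """Mean-pool the MTS rows of a residue embedding; carrier rows never contribute."""
    start, end = span
    if not (0 <= start < end <= embedding.matrix.shape[0]):
        raise EmbeddingError(
            f"{embedding.gene_id}: span [{start}, {end}) invalid for "
            f"{embedding.matrix.shape[0]} rows"
        )
    vector = embedding.matrix[start:end].mean(axis=0)
    return EmbeddedMTS(embedding.gene_id, vector, embedding.embedder_id)


def _residue_values(sequence: str, table: dict, x_policy: Optional[str]) -> np.ndarray:
    vals = np.empty(len(sequence))
    mean_val = float(np.mean(list(table.values())))
    for i, aa in enumerate(sequence):
        if aa in table:
            vals[i] = table[aa]
        elif aa == "X" and x_policy == "mean":
            vals[i] = mean_val
        else:
            raise EmbeddingError(f"unknown residue {aa!r} at position {i} (no 'X' policy set)")
    return vals


def _windowed_mean(values: np.ndarray, window: int) -> np.ndarray:
    """Centered running mean with edge truncation (windows shrink at termini)."""
    n = len(values)
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(values)])
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def _windowed_moment(hydro: np.ndarray, window: int, delta: float = HELIX_DELTA) -> np.ndarray:
    """Windowed hydrophobic moment μH on an idealized helix.

    For the (edge-truncated) window around each residue, with local
    index i starting at 0 and h centered on the window mean,
    μH = sqrt[(Σ h_i sin(iδ))² + (Σ h_i cos(iδ))²] / N.

    Centering makes μH a pure measure of amphipathy: a stretch of
    uniform hydrophobicity has no hydrophobic face and scores exactly
    zero, while periodic placement at ~3.6-residue spacing scores high.
    """
    n = len(hydro)
    half = window // 2
    out = np.empty(n)
    for c in range(n):
        lo, hi = max(c - half, 0), min(c + half + 1, n)
        h = hydro[lo:hi]
        h = h - h.mean()
        idx = np.arange(hi - lo)
        s = np.dot(h, np.sin(idx * delta))
        co = np.dot(h, np.cos(idx * delta))
        out[c] = np.hypot(s, co) / (hi - lo)
    return out


def surrogate_embed(
    sequence: str, window: int = 9, x_policy: Optional[str] = None
) -> np.ndarray:
    """Deterministic physicochemical per-residue embedding.

    Columns (in order): Kyte–Doolittle hydrophobicity; formal charge
    (+1 K/R, −1 D/E); hydroxylated indicator (S/T/Y); windowed mean
    hydrophobicity; windowed hydrophobic moment μH (δ = 100°); windowed
    net charge.  Windows are centered and edge-truncated.  Identical
    input gives bit-identical output.

    ``x_policy="mean"`` maps 'X' to each scale's mean value; by default
    'X' raises.
    """
    if not sequence:
        raise EmbeddingError("cannot embed an empty sequence")
    bad = set(sequence) - VALID_RESIDUES - ({"X"} if x_policy else set())
    if bad:
        raise EmbeddingError(f"invalid residue(s) {sorted(bad)}")
    kd = _residue_values(sequence, KYTE_DOOLITTLE, x_policy)
    charge = _residue_values(sequence, FORMAL_CHARGE, x_policy)
    hydroxyl = np.array([1.0 if aa in HYDROXYLATED else 0.0 for aa in sequence])
    return np.column_stack(
        [
            kd,
            charge,
            hydroxyl,
            _windowed_mean(kd, window),
            _windowed_moment(kd, window),
            _windowed_mean(charge, window),
        ]
    )


def make_surrogate(window: int = 9, x_policy: Optional[str] = None):
    """Return the surrogate embedder as a contract-conforming callable."""

    def _embed(sequence: str) -> np.ndarray:
        return surrogate_embed(sequence, window=window, x_policy=x_policy)

    return _embed


def load_carrier(path: str | Path) -> tuple[str, str]:
    """Read the first FASTA entry as (carrier_id, sequence)."""
    for entry in SeqIO.parse(str(path), "fasta"):
        return entry.id, str(entry.seq).upper()
    raise EmbeddingError(f"no FASTA entry in {path}")


def embed_catalog(
    catalog: Catalog,
    carrier: str = DHFR_MOUSE,
    carrier_id: str = "DHFR_mouse",
    embedder: Optional[Callable[[str], np.ndarray]] = None,
    embedder_id: str = "surrogate",
    window: int = 9,
) -> pd.DataFrame:
    """Fuse, embed, and pool every record of a catalog.

    Returns a DataFrame indexed by gene_id whose columns are the pooled
    feature dimensions (named for the surrogate, ``f0..f{d-1}``
    otherwise).
    """
    if embedder is None:
        embedder = make_surrogate(window=window)
        embedder_id = "surrogate"
    pooled = []
    ids = []
    for rec in catalog:
        fusion = build_fusion(rec, carrier, carrier_id)
        emb = embed_residues(fusion, embedder, embedder_id)
        pooled.append(pool_mts(emb, fusion.mts_span).vector)
        ids.append(rec.gene_id)
    mat = np.vstack(pooled) if pooled else np.empty((0, 0))
    if embedder_id == "surrogate" and mat.shape[1] == len(SURROGATE_FEATURES):
        cols = SURROGATE_FEATURES
    else:
        cols = [f"f{j}" for j in range(mat.shape[1])]
    return pd.DataFrame(mat, index=pd.Index(ids, name="gene_id"), columns=cols)
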