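"""Synthetic presequence catalogs, property tables, and perturbation data.

Sequences are built on an idealized amphipathic helix: hydrophobic
residues (L/F/I/V/A) spaced every ``hydrophobic_period`` positions
(≈3.6 residues per helical turn puts them on one face), K/R on a
controlled fraction of the remaining positions, S/T on another, D/E
only where allowed, and filler from {A, G, Q, N}.  Every sequence
starts with Met.  Groups therefore differ along exactly the axes a
matrix-targeting presequence is described by — net positive charge,
hydroxylated-residue content, hydrophobicity, and hydrophobic moment —
so ground-truth group structure is recoverable from physicochemical
embeddings.

Residue-class counts are allocated exactly (rounded fraction of the
remaining positions) and then shuffled, so within-group compositional
variance reflects length variation and placement, not sampling noise
in the composition itself.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from mtscape.catalog import Catalog, PresequenceRecord
from mtscape.group_stats import PROPERTY_COLUMNS
from mtscape.perturbation import PerturbationDataset

HYDROPHOBIC = "LFIVA"
POSITIVE = "KR"
HYDROXYL = "ST"
NEGATIVE = "DE"
FILLER = "AGQN"

#: realistic per-property baselines (units follow the property name)
PROPERTY_BASELINES = {
    "gravy_score": -0.4,
    "abundance_median": 2000.0,
    "aromaticity_score": 0.08,
    "codon_bias": 0.15,
    "protein_length": 450.0,
    "molecular_weight": 50000.0,
    "aliphatic_index": 85.0,
    "instability_index": 35.0,
    "protein_half_life": 10.0,
    "melting_temperature": 45.0,
}

DEFAULT_CATEGORIES = ("enzyme", "ribosomal", "carrier", "chaperone", "other")


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class GroupSpec:
    """Compositional recipe for one synthetic presequence group.

    ``hydrophobic_period`` is the spacing (in residues) between
    hydrophobic positions; 3.6 puts them on one helical face (high
    hydrophobic moment), larger values dilute hydrophobicity, smaller
    values concentrate it without amphipathy.  ``positive_fraction``,
    ``hydroxyl_fraction`` and ``negative_fraction`` partition the
    remaining (non-hydrophobic) positions; what is left is filler.
    """

    letter: str
    n: int = 30
    length_mean: float = 30.0
    length_sd: float = 4.0
    positive_fraction: float = 0.5
    hydroxyl_fraction: float = 0.15
    hydrophobic_period: float = 3.6
    negative_allowed: bool = False
    negative_fraction: float = 0.0

    def __post_init__(self) -> None:
        neg = self.negative_fraction if self.negative_allowed else 0.0
        if self.positive_fraction + self.hydroxyl_fraction + neg > 1.0 + 1e-9:
            raise SimulationError(f"group {self.letter}: residue-class fractions exceed 1")
        if self.n < 1 or self.length_mean < 8 or self.hydrophobic_period <= 1.0:
            raise SimulationError(f"group {self.letter}: infeasible spec")
        if self.negative_fraction and not self.negative_allowed:
            raise SimulationError(f"group {self.letter}: negative_fraction without negative_allowed")


def seven_groups_preset(n_per_group: int = 30) -> list[GroupSpec]:
    """Seven archetypal presequence groups, well separated in charge,
    hydroxyl content, hydrophobicity, and amphipathy."""
    return [
        # canonical long, strongly positive, amphipathic
        GroupSpec("A", n_per_group, 35, 4, 0.60, 0.15, 3.6, False),
        # short, positive, hydrophobic-poor (weak amphipathy)
        GroupSpec("B", n_per_group, 16, 2, 0.60, 0.15, 7.5, False),
        # hydroxyl-rich amphipathic, weakly charged
        GroupSpec("C", n_per_group, 30, 4, 0.15, 0.55, 3.6, False),
        # hydroxyl-rich, hydrophobic-poor
        GroupSpec("D", n_per_group, 25, 3, 0.15, 0.55, 7.5, False),
        # very hydrophobic, nearly uncharged
        GroupSpec("E", n_per_group, 40, 4, 0.15, 0.10, 2.2, False),
        # mixed positive + hydroxyl, amphipathic
        GroupSpec("F", n_per_group, 25, 3, 0.45, 0.45, 3.6, False),
        # atypical: acidic residues permitted, net charge ~ 0
        GroupSpec("G", n_per_group, 30, 4, 0.30, 0.10, 7.5, True, 0.30),
    ]


def _build_sequence(spec: GroupSpec, rng: np.random.Generator) -> str:
    length = int(round(rng.normal(spec.length_mean, spec.length_sd)))
    length = max(8, length)
    seq = [""] * length
    seq[0] = "M"
    # hydrophobic face: positions on a lattice with random phase
    phase = rng.uniform(1.0, 1.0 + spec.hydrophobic_period)
    hydro_pos = []
    j = 0
    while True:
        p = int(round(phase + j * spec.hydrophobic_period))
        if p >= length:
            break
        if p >= 1:
            hydro_pos.append(p)
        j += 1
    for p in hydro_pos:
        seq[p] = rng.choice(list(HYDROPHOBIC))
    remaining = [i for i in range(1, length) if not seq[i]]
    n_rem = len(remaining)
    n_pos = int(round(spec.positive_fraction * n_rem))
    n_hyd = int(round(spec.hydroxyl_fraction * n_rem))
    n_neg = int(round(spec.negative_fraction * n_rem)) if spec.negative_allowed else 0
    while n_pos + n_hyd + n_neg > n_rem:  # rounding overshoot
        n_hyd -= 1
    rng.shuffle(remaining)
    idx = 0
    for count, alphabet in ((n_pos, POSITIVE), (n_hyd, HYDROXYL), (n_neg, NEGATIVE)):
        for _ in range(count):
            seq[remaining[idx]] = rng.choice(list(alphabet))
            idx += 1
    for i in remaining[idx:]:
        seq[i] = rng.choice(list(FILLER))
    return "".join(seq)


def generate_catalog(
    specs: Sequence[GroupSpec], seed: int = 0
) -> tuple[Catalog, dict[str, str]]:
    """Generate a catalog with known group membership.

    Returns (catalog, truth) where truth maps gene_id → group letter.
    TargetP-style scores are drawn Uniform(0.3, 1.0) and
    times_identified as 1 + Poisson(2).  Deterministic given seed.
    """
    if not specs:
        raise SimulationError("need at least one group spec")
    records = []
    truth: dict[str, str] = {}
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
    for spec in specs:
        for i in range(spec.n):
            gene_id = f"syn{spec.letter}{i:03d}"
            records.append(
                PresequenceRecord(
                    gene_id=gene_id,
                    sequence=_build_sequence(spec, rng),
                    targetp_score=float(rng.uniform(0.3, 1.0)),
                    times_identified=int(1 + rng.poisson(2.0)),
                    source="synthetic",
                )
            )
            truth[gene_id] = spec.letter
    catalog = Catalog(records, metadata={"generator": "mtscape.simulate", "seed": str(seed)})
    return catalog, truth


def generate_properties(
    truth: Mapping[str, str],
    effects: Optional[Mapping[tuple[str, str], float]] = None,
    noise_sd: float = 1.0,
    seed: int = 0,
    category_probs: Optional[Mapping[str, Mapping[str, float]]] = None,
) -> pd.DataFrame:
    """Per-protein property table with optional group-specific shifts.

    ``effects`` maps (letter, property) → additive shift on that
    property's baseline for members of the group.  Each numeric value
    is Normal(baseline + shift, noise_sd); ``functional_category`` is
    drawn from a per-group categorical distribution (uniform over the
    default categories when not supplied).
    """
    effects = dict(effects or {})
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    gene_ids = list(truth)
    data: dict[str, list] = {col: [] for col in PROPERTY_COLUMNS}
    cats = []
    for g in gene_ids:
        letter = truth[g]
        for col in PROPERTY_COLUMNS:
            base = PROPERTY_BASELINES[col] + effects.get((letter, col), 0.0)
            data[col].append(rng.normal(base, noise_sd))
        if category_probs and letter in category_probs:
            probs = category_probs[letter]
            names = list(probs)
            p = np.array([probs[c] for c in names], dtype=float)
            cats.append(str(rng.choice(names, p=p / p.sum())))
        else:
            cats.append(str(rng.choice(DEFAULT_CATEGORIES)))
    df = pd.DataFrame(data, index=pd.Index(gene_ids, name="gene_id"))
    df["functional_category"] = cats
    return df


def generate_perturbation(
    truth: Mapping[str, str],
    affected: Optional[Mapping[str, float]] = None,
    noise_sd: float = 0.3,
    conditions: int = 1,
    seed: int = 0,
    dropout: float = 0.0,
) -> list[PerturbationDataset]:
    """Log2 fold-change tables with group-targeted effects.

    Members of a group in ``affected`` get fc ~ Normal(effect mean,
    noise_sd); everyone else Normal(0, noise_sd).  ``dropout`` removes
    a random fraction of proteins per condition to emulate partial
    quantification.
    """
    if noise_sd <= 0:
        raise SimulationError("noise_sd must be positive")
    if not 0.0 <= dropout <= 1.0:
        raise SimulationError("dropout must lie in [0, 1]")
    affected = dict(affected or {})
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    gene_ids = list(truth)
    out = []
    for c in range(conditions):
        means = np.array([affected.get(truth[g], 0.0) for g in gene_ids])
        fc = rng.normal(means, noise_sd)
        keep = rng.random(len(gene_ids)) >= dropout
        series = pd.Series(fc[keep], index=pd.Index(np.array(gene_ids)[keep], name="gene_id"))
        out.append(
            PerturbationDataset(f"cond{c + 1:02d}", series, source="synthetic")
        )
    return out
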