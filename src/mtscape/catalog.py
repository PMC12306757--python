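"""Presequence catalog I/O and curation.

A catalog is an ordered collection of presequence records (gene id,
amino-acid sequence, TargetP-style score, times-identified count).
Curation reproduces the rules used for the yeast processing-site
dataset: a score filter, a minimum length, deduplication keeping the
most-often-identified (then longest) presequence per gene, and removal
of trivial entries whose "presequence" is a bare initiator methionine.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO

VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: 'X' marks an unknown residue; allowed in catalogs, embedders may reject it.
VALID_WITH_X = VALID_RESIDUES | {"X"}

CATALOG_COLUMNS = ["gene_id", "sequence", "targetp_score", "times_identified", "length", "source"]


class CatalogError(ValueError):
    """Malformed catalog input (bad row, bad residue, bad score)."""


@dataclass(frozen=True)
class PresequenceRecord:
    """One curated presequence (MTS).

    Parameters
    ----------
    gene_id : str
        Gene identifier (e.g. systematic or standard yeast name).
    sequence : str
        Amino-acid sequence, uppercase one-letter codes ('X' allowed).
    targetp_score : float or None
        Probability-like targeting score in [0, 1]; ``None`` if absent.
    times_identified : int or None
        How often this presequence form was observed; ``None`` if absent.
    source : str
        Provenance tag, e.g. ``"yeast_ref"``, ``"manual"``, ``"synthetic"``.
    """

    gene_id: str
    sequence: str
    targetp_score: Optional[float] = None
    times_identified: Optional[int] = None
    source: str = "unknown"

    def __post_init__(self) -> None:
        bad = set(self.sequence) - VALID_WITH_X
        if bad:
            raise CatalogError(
                f"record {self.gene_id!r}: invalid residue(s) {sorted(bad)} in sequence"
            )
        if self.targetp_score is not None and not (0.0 <= self.targetp_score <= 1.0):
            raise CatalogError(
                f"record {self.gene_id!r}: targetp_score {self.targetp_score} outside [0, 1]"
            )
        if self.times_identified is not None and self.times_identified < 0:
            raise CatalogError(f"record {self.gene_id!r}: negative times_identified")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class Catalog:
    """Ordered presequence records plus free-form curation metadata."""

    records: list[PresequenceRecord] = field(default_factory=list)
    metadata: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def gene_ids(self) -> list[str]:
        return [r.gene_id for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [r.gene_id for r in self.records],
                "sequence": [r.sequence for r in self.records],
                "targetp_score": [r.targetp_score for r in self.records],
                "times_identified": [r.times_identified for r in self.records],
                "length": [r.length for r in self.records],
                "source": [r.source for r in self.records],
            }
        )


def _parse_score(value, where: str) -> Optional[float]:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    try:
        return float(value)
    except (TypeError, ValueError) as exc:
        raise CatalogError(f"{where}: cannot parse targetp_score {value!r}") from exc


def _parse_times(value, where: str) -> Optional[int]:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    try:
        return int(float(value))
    except (TypeError, ValueError) as exc:
        raise CatalogError(f"{where}: cannot parse times_identified {value!r}") from exc


def load_catalog(path: str | Path, format: str = "tsv") -> Catalog:
    """Read a catalog from TSV, CSV, or FASTA.

    Delimited files need at least ``gene_id`` and ``sequence`` columns;
    ``targetp_score`` / ``times_identified`` are optional and recorded
    as absent (not zero) when missing.  FASTA headers use the dialect
    ``>gene_id score=0.87 times=5``.

    Raises
    ------
    CatalogError
        On a malformed row (named by line number) or a sequence with a
        character outside the 20 standard residues plus 'X'.
    """
    path = Path(path)
    if format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        try:
            df = pd.read_csv(path, sep=sep, dtype={"gene_id": str, "sequence": str})
        except pd.errors.EmptyDataError:
            return Catalog(metadata={"source_file": str(path)})
        missing = {"gene_id", "sequence"} - set(df.columns)
        if missing:
            raise CatalogError(f"{path}: missing required column(s) {sorted(missing)}")
        records = []
        for idx, row in df.iterrows():
            where = f"{path} line {idx + 2}"  # +1 header, +1 1-based
            if pd.isna(row["gene_id"]) or pd.isna(row["sequence"]):
                raise CatalogError(f"{where}: missing gene_id or sequence")
            try:
                rec = PresequenceRecord(
                    gene_id=str(row["gene_id"]),
                    sequence=str(row["sequence"]).upper(),
                    targetp_score=_parse_score(row.get("targetp_score"), where),
                    times_identified=_parse_times(row.get("times_identified"), where),
                    source=str(row["source"]) if "source" in df.columns and pd.notna(row.get("source")) else "file",
                )
            except CatalogError as exc:
                raise CatalogError(f"{where}: {exc}") from exc
            records.append(rec)
        return Catalog(records, metadata={"source_file": str(path), "format": format})
    elif format == "fasta":
        records = []
        for entry in SeqIO.parse(str(path), "fasta"):
            tokens = entry.description.split()
            score = None
            times = None
            for tok in tokens[1:]:
                if tok.startswith("score="):
                    score = _parse_score(tok[6:], entry.id)
                elif tok.startswith("times="):
                    times = _parse_times(tok[6:], entry.id)
            records.append(
                PresequenceRecord(
                    gene_id=entry.id,
                    sequence=str(entry.seq).upper(),
                    targetp_score=score,
                    times_identified=times,
                    source="fasta",
                )
            )
        return Catalog(records, metadata={"source_file": str(path), "format": "fasta"})
    raise ValueError(f"unknown format {format!r}; expected tsv, csv, or fasta")


def write_catalog(catalog: Catalog, path: str | Path) -> None:
    """Write a catalog as TSV (UTF-8, LF) with full-precision scores."""
    path = Path(path)
    buf = io.StringIO()
    buf.write("\t".join(CATALOG_COLUMNS) + "\n")
    for r in catalog.records:
        score = "" if r.targetp_score is None else repr(r.targetp_score)
        times = "" if r.times_identified is None else str(r.times_identified)
        buf.write(f"{r.gene_id}\t{r.sequence}\t{score}\t{times}\t{r.length}\t{r.source}\n")
    path.write_text(buf.getvalue(), encoding="utf-8", newline="\n")


def filter_records(catalog: Catalog, min_score: float = 0.3, min_length: int = 8) -> Catalog:
    """Keep records with targeting score ≥ ``min_score`` and length ≥ ``min_length``.

    Records lacking a score cannot pass the score filter and are
    dropped; counts of dropped records by reason are appended to the
    returned catalog's metadata (``dropped_no_score``,
    ``dropped_low_score``, ``dropped_short``).
    """
    kept: list[PresequenceRecord] = []
    no_score = low_score = short = 0
    for r in catalog.records:
        if r.targetp_score is None:
            no_score += 1
        elif r.targetp_score < min_score:
            low_score += 1
        elif r.length < min_length:
            short += 1
        else:
            kept.append(r)
    meta = dict(catalog.metadata)
    meta.update(
        {
            "filter_min_score": repr(min_score),
            "filter_min_length": str(min_length),
            "dropped_no_score": str(no_score),
            "dropped_low_score": str(low_score),
            "dropped_short": str(short),
        }
    )
    return Catalog(kept, meta)


def deduplicate(catalog: Catalog) -> Catalog:
    """One record per gene: most often identified, then longest, then first seen.

    A missing times_identified counts as 0 for the comparison.
    """
    best: dict[str, PresequenceRecord] = {}
    order: list[str] = []
    for r in catalog.records:
        if r.gene_id not in best:
            best[r.gene_id] = r
            order.append(r.gene_id)
            continue
        cur = best[r.gene_id]
        r_times = r.times_identified or 0
        c_times = cur.times_identified or 0
        if (r_times, r.length) > (c_times, cur.length):
            best[r.gene_id] = r
    meta = dict(catalog.metadata)
    meta["deduplicated_from"] = str(len(catalog.records))
    return Catalog([best[g] for g in order], meta)


def drop_trivial(catalog: Catalog) -> Catalog:
    """Remove length-1 presequences (bare Met) and empty sequences."""
    kept = [r for r in catalog.records if r.length > 1]
    meta = dict(catalog.metadata)
    meta["dropped_trivial"] = str(len(catalog.records) - len(kept))
    return Catalog(kept, meta)


def add_manual(catalog: Catalog, record: PresequenceRecord) -> Catalog:
    """Append a manually curated record, replacing any record with the same gene_id."""
    record = replace(record, source="manual")
    kept = [r for r in catalog.records if r.gene_id != record.gene_id]
    replaced = len(kept) != len(catalog.records)
    meta = dict(catalog.metadata)
    meta[f"manual_{record.gene_id}"] = "replaced" if replaced else "added"
    return Catalog(kept + [record], meta)


def curate(
    catalog: Catalog,
    min_score: float = 0.3,
    min_length: int = 8,
    manual: Iterable[PresequenceRecord] = (),
) -> Catalog:
    """Full curation: filter → deduplicate → drop trivial → add manual entries."""
    out = drop_trivial(deduplicate(filter_records(catalog, min_score, min_length)))
    for rec in manual:
        out = add_manual(out, rec)
    out.metadata["curated_count"] = str(len(out))
    return out
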