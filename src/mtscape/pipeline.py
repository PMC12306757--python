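"""End-to-end orchestration: curate → embed → landscape → groupstats → validate.

``run_all`` executes every stage on files named in a :class:`RunConfig`,
writes each stage's TSV outputs into the output directory, and records
a manifest JSON (input digests, all parameters, seeds, package
version) sufficient to re-execute an identical run.  Stages can be
re-run individually from the intermediates via the stage functions or
the ``mts`` CLI subcommands.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from mtscape import catalog as cat
from mtscape import embedding as emb
from mtscape import group_stats as gs
from mtscape import landscape as land
from mtscape import perturbation as pert

log = logging.getLogger("mtscape")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Flat configuration for a full run; every stochastic stage has a seed."""

    catalog_path: str = ""
    catalog_format: str = "tsv"
    carrier_path: str = ""  # empty → bundled mouse DHFR
    properties_path: str = ""
    datasets_path: str = ""
    out_dir: str = "mts_run"
    min_score: float = 0.3
    min_length: int = 8
    window: int = 9
    n_neighbors: int = 15
    min_dist: float = 0.2
    spread: float = 2.0
    learning_rate: float = 0.5
    n_epochs: int = 1000
    gamma: float = 1.1
    restarts: int = 20
    k: Optional[int] = None  # None → select automatically
    k_min: int = 2
    k_max: int = 12
    alpha: float = 0.05
    n_iter: int = 99_999
    seed: int = land.DEFAULT_SEED

    def validate(self, require: tuple[str, ...] = ("catalog_path",)) -> None:
        for name in require:
            if not getattr(self, name):
                raise ConfigError(f"config field {name!r} is required but empty")
        for name in ("catalog_path", "carrier_path", "properties_path", "datasets_path"):
            value = getattr(self, name)
            if value and not Path(value).exists():
                raise ConfigError(f"config field {name!r}: no such file {value!r}")

    @classmethod
    def from_json(cls, path: str | Path, **overrides) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _digest(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def run_all(config: RunConfig) -> dict:
    """Execute all stages in order; returns the manifest dict.

    Any stage error aborts with the stage named in the exception;
    outputs of completed stages are left intact.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "inputs": {},
        "stages": [],
        "version": _version(),
    }
    for name in ("catalog_path", "carrier_path", "properties_path", "datasets_path"):
        value = getattr(config, name)
        if value:
            manifest["inputs"][name] = {"path": value, "sha256_16": _digest(value)}

    stage = "curate"
    try:
        raw = cat.load_catalog(config.catalog_path, config.catalog_format)
        curated = cat.curate(raw, min_score=config.min_score, min_length=config.min_length)
        cat.write_catalog(curated, out / "curated.tsv")
        log.info("curate: %d -> %d records (%s)", len(raw), len(curated), curated.metadata)
        manifest["stages"].append({"stage": stage, "n_in": len(raw), "n_out": len(curated)})

        stage = "embed"
        if config.carrier_path:
            carrier_id, carrier = emb.load_carrier(config.carrier_path)
        else:
            carrier_id, carrier = "DHFR_mouse", emb.DHFR_MOUSE
        vectors = emb.embed_catalog(
            curated, carrier=carrier, carrier_id=carrier_id, window=config.window
        )
        vectors.to_csv(out / "vectors.tsv", sep="\t")
        (out / "embedder.json").write_text(
            json.dumps({"embedder_id": "surrogate", "window": config.window,
                        "carrier_id": carrier_id}, indent=2)
        )
        manifest["stages"].append({"stage": stage, "n": len(vectors), "d": vectors.shape[1]})

        stage = "landscape"
        params = land.ProjectionParams(
            n_neighbors=config.n_neighbors,
            min_dist=config.min_dist,
            spread=config.spread,
            learning_rate=config.learning_rate,
            n_epochs=config.n_epochs,
            seed=config.seed,
        )
        points, model = land.fit_landscape(
            vectors,
            params=params,
            k=config.k,
            k_range=(config.k_min, config.k_max),
            gamma=config.gamma,
            restarts=config.restarts,
            seed=config.seed,
        )
        clusters = points.copy()
        clusters["label"] = model.labels
        clusters["letter"] = model.assignments().to_numpy()
        clusters.to_csv(out / "clusters.tsv", sep="\t")
        if model.selection_trace is not None:
            model.selection_trace.to_csv(out / "selection_trace.tsv", sep="\t", index=False)
        log.info("landscape: k=%d (low_confidence=%s)", model.k, model.low_confidence)
        manifest["stages"].append({"stage": stage, "k": model.k, "seed": config.seed})

        if config.properties_path:
            stage = "groupstats"
            props = pd.read_csv(config.properties_path, sep="\t", index_col="gene_id")
            results = gs.property_scan(props, model, alpha=config.alpha)
            frames = []
            for r in results:
                if r.pairwise.empty:
                    continue
                pw = r.pairwise.copy()
                pw.insert(0, "property", r.property)
                pw.insert(1, "kw_statistic", r.kw_statistic)
                pw.insert(2, "kw_p", r.kw_p)
                frames.append(pw)
            summary = pd.DataFrame(
                {
                    "property": [r.property for r in results],
                    "kw_statistic": [r.kw_statistic for r in results],
                    "kw_p": [r.kw_p for r in results],
                }
            )
            summary.to_csv(out / "property_kw.tsv", sep="\t", index=False)
            if frames:
                pd.concat(frames, ignore_index=True).to_csv(
                    out / "property_posthoc.tsv", sep="\t", index=False
                )
            if "functional_category" in props.columns:
                gs.category_composition(props, model).to_csv(
                    out / "category_composition.tsv", sep="\t", index=False
                )
            manifest["stages"].append({"stage": stage, "n_properties": len(results)})

        if config.datasets_path:
            stage = "validate"
            datasets = pert.load_datasets(config.datasets_path, layout="long")
            table = pert.run_validation(
                datasets, model, n_iter=config.n_iter, alpha=config.alpha, seed=config.seed
            )
            table.to_csv(out / "perturbation_results.tsv", sep="\t", index=False)
            manifest["stages"].append(
                {"stage": stage, "n_conditions": len(datasets), "n_iter": config.n_iter}
            )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _version() -> str:
    from mtscape import __version__

    return __version__
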