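"""End-to-end run: ingest → embed → pair → filter → classify → coverage → topics → export.

One structured configuration drives the whole run; every artifact lands in
the output directory stamped with the configuration digest and the seed so
a run can be reproduced from its report alone.
"""

from __future__ import annotations

import hashlib
import json
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import harmonization, pairing, rating_study, topics
from .embedding import embed_items, make_backend
from .errors import ConfigurationError
from .items import ItemSet, load_item_table, validate_items, write_items


@dataclass
class RunConfig:
    """Declarative description of a pipeline run."""

    input_path: str
    column_map: dict = field(default_factory=lambda: {"instrument": "instrument", "text": "text"})
    input_format: str | None = None
    backend: str = "hash-ngram"
    backend_params: dict = field(default_factory=dict)
    scope: str = "all"
    tau: float = harmonization.DEFAULT_TAU
    bands_positive: tuple[float, float] = (0.676, 0.912)
    bands_negative: tuple[float, float] = (0.737, 0.800)
    topics_k: int = 8
    group_size: int = 5
    n_final: int = 20
    seed: int = 0
    output_dir: str = "semharm_out"
    network_format: str = "graphml"
    run_study_design: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.bands_positive = tuple(cfg.bands_positive)  # type: ignore[assignment]
        cfg.bands_negative = tuple(cfg.bands_negative)  # type: ignore[assignment]
        return cfg

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode("utf-8")).hexdigest()[:16]


def substream_seed(seed: int, name: str) -> int:
    """Named, reproducible sub-seed below 2**31 derived from the run seed."""
    return (int(seed) * 1_000_003 + zlib.crc32(name.encode("utf-8"))) % (2**31 - 1)


def run_pipeline(config: RunConfig, items: ItemSet | None = None) -> Path:
    """Execute every stage; return the output directory.

    ``items`` may be passed directly (e.g. a generated corpus) to bypass
    file ingestion.  On a stage failure, artifacts written so far are kept
    and a ``FAILED`` marker names the stage.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "pipeline.log"
    report: dict = {"config_digest": config.digest(), "seed": config.seed, "stages": {}}
    log_lines = [f"# semharm run digest={config.digest()} seed={config.seed}"]

    def stage(name: str, counts: dict) -> None:
        report["stages"][name] = counts
        log_lines.append(
            f"{name}\t" + "\t".join(f"{k}={v}" for k, v in counts.items())
        )
        log_path.write_text("\n".join(log_lines) + "\n")

    current = "ingest"
    t0 = time.time()
    try:
        if items is None:
            items = load_item_table(
                config.input_path, column_map=config.column_map, format=config.input_format
            )
        write_items(items, out / "items.csv")
        validation = validate_items(items)
        stage("ingest", {"n_items": len(items), "n_instruments": len(validation.per_instrument)})

        current = "embed"
        backend = make_backend(config.backend, **config.backend_params)
        emb = embed_items(items, backend, normalize=True)
        emb_frame = pd.DataFrame(emb.vectors, index=pd.Index(emb.item_ids, name="item_id"))
        emb_frame.to_csv(out / "embeddings.csv")
        stage("embed", {"n_vectors": len(emb), "dimension": emb.dimension,
                        "n_zero": len(emb.zero_ids)})

        current = "pair"
        pairs = pairing.build_scored_pairs(items, emb, scope=config.scope)
        pairing.export_pairs_csv(pairs, out / "pairs_scored.csv")
        summary = pairing.summarize_scores(pairs)
        (out / "score_summary.json").write_text(json.dumps(summary.to_dict(), indent=2))
        stage("pair", {"n_pairs": len(pairs), "mean": round(summary.mean, 6),
                       "sd": round(summary.sd, 6)})

        current = "filter"
        candidates = harmonization.filter_by_threshold(pairs, tau=config.tau)
        stage("filter", {"tau": config.tau, "n_candidates": len(candidates)})

        current = "classify"
        bands = harmonization.ClassificationBands(
            positive=config.bands_positive, negative=config.bands_negative,
            source="run config",
        )
        classified, automation = harmonization.classify_bands(pairs, bands)
        pairing.export_pairs_csv(
            classified[classified["score"] > config.tau], out / "candidates.csv"
        )
        automation.to_json(out / "automation.json")
        stage("classify", {"n_classified": automation.n_total,
                           "n_positive": automation.n_positive,
                           "n_negative": automation.n_negative,
                           "n_uncertain": automation.n_uncertain})

        current = "coverage"
        cov = harmonization.coverage(pairs, items, tau=config.tau)
        cov.table.to_csv(out / "coverage.csv", index=False)
        cov.matrix.to_csv(out / "coverage_matrix.csv")
        stage("coverage", {"n_instruments": len(cov.table),
                           "n_fully_covered": int((cov.table["coverage_percent"] == 100).sum())})

        current = "topics"
        k = min(config.topics_k, len(items))
        assignment = topics.cluster_embeddings(emb, k=k, seed=substream_seed(config.seed, "topics"))
        terms = topics.ctfidf_terms(items.texts, assignment, top_n=10)
        terms.to_frame().to_csv(out / "topics.csv", index=False)
        proj = topics.project_2d(emb, method="pca")
        proj.to_csv(out / "projection.csv", index=False)
        stage("topics", {"k": k})

        current = "study"
        if config.run_study_design:
            sample = rating_study.design_study(
                pairs,
                group_size=config.group_size,
                n_final=config.n_final,
                seed=substream_seed(config.seed, "study"),
                clamp=True,
            )
            sample.final.to_csv(out / "study_sample.csv", index=False)
            stage("study", {"n_preselected": sample.n_preselected, "n_final": sample.n_final})

        current = "export"
        suffix = "graphml" if config.network_format == "graphml" else "json"
        harmonization.export_network(
            candidates, items, out / f"network.{suffix}", format=config.network_format
        )
        stage("export", {"n_nodes": len(items), "n_edges": len(candidates)})
    except Exception as exc:
        (out / "FAILED").write_text(f"stage={current}\nerror={exc}\n")
        raise RuntimeError(f"pipeline failed at stage {current!r}: {exc}") from exc

    report["runtime_s"] = round(time.time() - t0, 3)
    (out / "run_report.json").write_text(json.dumps(report, indent=2))
    return out
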