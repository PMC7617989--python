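"""End-to-end reproducible pipeline run with manifest and logging.

``run_pipeline`` reads a YAML run configuration, executes counts →
normalization → enrichment → hit calling through :class:`ScreenModel`, and
writes the gene table, guide table, hit list, a JSON summary and a
provenance manifest (input checksums, config echo, tool version). Outputs
are staged in a temporary directory and moved into place only on success,
so a failing run never leaves truncated files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .enrich import DetectionRule
from .hits import HitRuleConfig
from .io import read_annotation, write_table
from .model import ScreenModel

log = logging.getLogger("metscreen")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    library: Path
    counts: Path
    metadata: Path
    outdir: Path
    annotation: Path | None = None
    annotation_predicates: list[str] = field(default_factory=list)
    keep_missing_annotation: bool = False
    delimiter: str = "\t"
    min_raw_count: int = 1
    pseudocount: float = 0.5
    normalization: str = "cpm"
    test: str = "pooled"
    multi_guide_min: int = 2
    lung_guide_max_for_rescue: int = 2
    require_per_guide_brain_gt_lung: bool = True
    log_level: str = "INFO"
    seed: int | None = None  # reserved for resampling extensions

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("library", "counts", "metadata", "outdir", "annotation"):
            if raw.get(key) is not None:
                raw[key] = Path(raw[key])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis; returns the manifest dict."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    inputs = {"library": cfg.library, "counts": cfg.counts, "metadata": cfg.metadata}
    if cfg.annotation is not None:
        inputs["annotation"] = cfg.annotation
    for name, path in inputs.items():
        if not Path(path).exists():
            raise FileNotFoundError(f"{name} file not found: {path}")

    outdir_early = Path(cfg.outdir)
    outdir_early.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(outdir_early / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)

    log.info("loading inputs")
    model = ScreenModel.from_files(
        cfg.counts,
        cfg.library,
        cfg.metadata,
        delimiter=cfg.delimiter,
        detection=DetectionRule(min_raw_count=cfg.min_raw_count),
        pseudocount=cfg.pseudocount,
        normalization=cfg.normalization,
    )
    log.info("fitting enrichment model")
    results = model.fit(
        hit_rule=HitRuleConfig(
            multi_guide_min=cfg.multi_guide_min,
            lung_guide_max_for_rescue=cfg.lung_guide_max_for_rescue,
            require_per_guide_brain_gt_lung=cfg.require_per_guide_brain_gt_lung,
        ),
        test=cfg.test,
    )
    hits = results.passed()
    if cfg.annotation is not None and cfg.annotation_predicates:
        ann = read_annotation(cfg.annotation, delimiter=cfg.delimiter)
        hits = results.filter_hits(
            ann, cfg.annotation_predicates, cfg.keep_missing_annotation
        )
        log.info("annotation filter kept %d of %d hits", len(hits), int(results.hits["passed"].sum()))

    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = Path(tempfile.mkdtemp(prefix=".metscreen-", dir=outdir))
    try:
        write_table(results.gene_table, stage / "gene_table.tsv")
        write_table(results.guide_table, stage / "guide_table.tsv")
        write_table(results.hits, stage / "gene_calls.tsv")
        write_table(hits, stage / "hits.tsv")
        branch_counts = results.hits["branch"].value_counts().to_dict()
        summary = {
            "n_genes_tested": int(len(results.gene_table)),
            "n_hits": int(results.hits["passed"].sum()),
            "n_hits_after_annotation": int(len(hits)),
            "branch_counts": {k: int(v) for k, v in branch_counts.items()},
        }
        (stage / "summary.json").write_text(json.dumps(summary, indent=1))
        manifest = {
            "tool": "metscreen",
            "version": __version__,
            "inputs": {k: {"path": str(v), "sha256": _sha256(Path(v))} for k, v in inputs.items()},
            "config": {
                k: (str(v) if isinstance(v, Path) else v)
                for k, v in cfg.__dict__.items()
            },
            "outputs": [
                "gene_table.tsv", "guide_table.tsv", "gene_calls.tsv",
                "hits.tsv", "summary.json",
            ],
        }
        (stage / "manifest.json").write_text(json.dumps(manifest, indent=1))
        for name in manifest["outputs"] + ["manifest.json"]:
            shutil.move(str(stage / name), str(outdir / name))
    finally:
        shutil.rmtree(stage, ignore_errors=True)
        log.removeHandler(fh)
        fh.close()
    (stage_cfg := outdir / "run_config.yaml").write_text(
        yaml.safe_dump({k: (str(v) if isinstance(v, Path) else v) for k, v in cfg.__dict__.items()})
    )
    log.info("wrote results to %s", outdir)
    return manifest
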