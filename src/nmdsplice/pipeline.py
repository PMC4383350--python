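"""End-to-end orchestration: annotate -> quantify -> diff -> report.

A run is driven by one structured config (YAML or dict) and writes every
stage artifact plus a manifest (config snapshot, input/output checksums,
per-stage record counts) into the output directory. Deterministic stages
produce identical output checksums on rerun with identical inputs and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import io as nio
from .annotation import (
    build_event_catalog,
    enumerate_candidate_junctions,
    group_genes,
    identify_constitutive_junctions,
    merge_annotations,
    read_gtf,
)
from .diffsplice import Thresholds, call_events, summarize_global
from .models import EventClass
from .quantify import (
    FilterStats,
    count_event_reads,
    filter_alignments,
    iter_sam,
    psi_table,
)
from .report import render_report
from .simulate import SimulationConfig, emit_sam, generate_annotation, simulate_counts

__version__ = "0.1.0"
logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Validated run configuration. Either ``inputs`` (gtf plus sam/counts
    per condition) or ``simulate`` must be given."""

    seed: int = 0
    gtf: Optional[str] = None
    gtf_b: Optional[str] = None
    orf_table: Optional[str] = None
    sam: Optional[dict[str, str]] = None        # {"cond1": path, "cond2": path}
    counts: Optional[dict[str, str]] = None
    simulate: Optional[dict] = None
    emit_sam: bool = False
    event_classes: Optional[list[str]] = None
    min_mapq_exclusive: int = 0
    min_overhang: int = 6
    min_identifying_reads: int = 20
    min_delta_psi: float = 0.10
    min_bayes_factor: float = 5.0
    ptc_distance: int = 50

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        bad = set(d) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def thresholds(self) -> Thresholds:
        return Thresholds(self.min_identifying_reads, self.min_delta_psi, self.min_bayes_factor)

    def validate(self) -> None:
        if self.simulate is None:
            if self.gtf is None:
                raise ValueError("config needs either 'gtf' or a 'simulate' section")
            if (self.sam is None) == (self.counts is None):
                raise ValueError("provide exactly one of 'sam' or 'counts' per condition")
            for mapping in (self.sam, self.counts):
                if mapping is not None and set(mapping) != {"cond1", "cond2"}:
                    raise ValueError("sam/counts must map exactly cond1 and cond2")


@dataclass
class RunResult:
    out_dir: Path
    catalog: list
    psi1: list
    psi2: list
    calls: list
    summary: object
    manifest: dict
    outputs: dict[str, Path] = field(default_factory=dict)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig | dict, out_dir: str | Path) -> RunResult:
    """Execute the full pipeline and write all artifacts under ``out_dir``.

    Raises :class:`StageError` naming the failing stage; the CLI converts
    that into a nonzero exit status.
    """
    if isinstance(config, dict):
        config = PipelineConfig.from_dict(config)
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "nmdsplice",
        "version": __version__,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": {k: v for k, v in vars(config).items()},
        "inputs": {},
        "stages": {},
        "outputs": {},
    }
    outputs: dict[str, Path] = {}

    def record(name: str, path: Path) -> Path:
        outputs[name] = path
        return path

    # --- simulate (optional) --------------------------------------------
    counts_paths = dict(config.counts or {})
    sam_paths = dict(config.sam or {})
    gtf_path = config.gtf
    orf_path = config.orf_table
    if config.simulate is not None:
        try:
            sim_cfg = SimulationConfig.from_dict({"seed": config.seed, **config.simulate})
            sim = generate_annotation(sim_cfg)
            rng = np.random.default_rng(sim_cfg.seed + 1)
            c1, c2 = simulate_counts(sim_cfg, sim.truth, rng)
            gtf_path = str(record("gtf", out / "simulated.gtf"))
            Path(gtf_path).write_text(sim.gtf_text)
            orf_path = str(record("orf_table", out / "simulated_orfs.tsv"))
            nio.write_orf_table(sim.orf_table, orf_path)
            nio.write_truth(sim.truth, record("truth", out / "truth.tsv"))
            for cond, counts in (("cond1", c1), ("cond2", c2)):
                p = record(f"counts_{cond}", out / f"counts_{cond}.tsv")
                nio.write_counts(counts, p)
                counts_paths[cond] = str(p)
            if config.emit_sam:
                for cond, counts in (("cond1", c1), ("cond2", c2)):
                    p = record(f"sam_{cond}", out / f"reads_{cond}.sam")
                    p.write_text(emit_sam(sim, counts))
                    sam_paths[cond] = str(p)
                counts_paths = {}
            manifest["stages"]["simulate"] = {
                "n_genes": sim_cfg.n_genes,
                "n_transcripts": len(sim.transcripts),
                "n_truth_events": len(sim.truth.events),
            }
        except Exception as exc:
            raise StageError("simulate", exc) from exc

    for name, p in {"gtf": gtf_path, "gtf_b": config.gtf_b, "orf_table": orf_path,
                    **{f"sam_{k}": v for k, v in sam_paths.items()},
                    **{f"counts_{k}": v for k, v in counts_paths.items()}}.items():
        if p:
            manifest["inputs"][name] = {"path": str(p), "sha256": _sha256(Path(p))}

    # --- annotate --------------------------------------------------------
    try:
        models = read_gtf(gtf_path, source="annotationA")
        if config.gtf_b:
            models = merge_annotations(models, read_gtf(config.gtf_b, source="annotationB"))
        orf_table = nio.read_orf_table(orf_path) if orf_path else None
        genes = group_genes(models)
        constitutive = identify_constitutive_junctions(genes)
        candidates = {g.gene_id: enumerate_candidate_junctions(g) for g in genes}
        classes = (
            {EventClass(c) for c in config.event_classes}
            if config.event_classes
            else ({EventClass(c) for c in config.simulate.get(
                "event_class_mix", SimulationConfig().event_class_mix)}
                  if config.simulate is not None else None)
        )
        catalog = build_event_catalog(
            genes, constitutive, candidates, orf_table,
            ptc_distance=config.ptc_distance, classes=classes,
        )
        nio.write_catalog(catalog, record("catalog", out / "event_catalog.tsv"))
        all_junctions = set()
        for g in genes:
            all_junctions |= {j for j in candidates[g.gene_id] if not j.annotated}
        all_junctions |= constitutive
        nio.write_junction_bed(all_junctions, record("junctions", out / "junctions.bed"))
        manifest["stages"]["annotate"] = {
            "n_transcripts": len(models),
            "n_genes": len(genes),
            "n_constitutive_junctions": sum(j.constitutive for j in constitutive),
            "n_events": len(catalog),
            "n_eligible_events": sum(e.eligible for e in catalog),
        }
    except Exception as exc:
        raise StageError("annotate", exc) from exc

    # --- quantify --------------------------------------------------------
    psi = {}
    try:
        for cond in ("cond1", "cond2"):
            if sam_paths:
                stats = FilterStats()
                reads = filter_alignments(
                    iter_sam(sam_paths[cond]),
                    config.min_mapq_exclusive, config.min_overhang, stats,
                )
                counts = count_event_reads(reads, catalog, sample_id=cond,
                                           retention_flank=config.min_overhang)
                nio.write_counts(counts, record(f"counted_{cond}", out / f"counted_{cond}.tsv"))
                manifest["stages"][f"filter_{cond}"] = vars(stats)
            else:
                counts = nio.read_counts(counts_paths[cond], sample_id=None)
                counts.sample_id = cond
            psi[cond] = psi_table(counts, catalog)
            nio.write_psi(psi[cond], record(f"psi_{cond}", out / f"psi_{cond}.tsv"))
        manifest["stages"]["quantify"] = {"n_psi_rows": len(psi["cond1"])}
    except Exception as exc:
        raise StageError("quantify", exc) from exc

    # --- diff ------------------------------------------------------------
    try:
        thresholds = config.thresholds()
        calls = call_events(psi["cond1"], psi["cond2"], catalog, thresholds)
        summary = summarize_global(calls, catalog, thresholds)
        nio.write_calls(calls, record("calls", out / "calls.tsv"), catalog)
        nio.write_summary(summary, record("summary", out / "summary.tsv"))
        manifest["stages"]["diff"] = {
            "n_calls": len(calls),
            "n_tested": sum(c.passes_reads for c in calls),
            "n_called": sum(c.called for c in calls),
        }
    except Exception as exc:
        raise StageError("diff", exc) from exc

    # --- report ----------------------------------------------------------
    try:
        text = render_report(calls, summary, catalog)
        record("report", out / "report.txt").write_text(text)
    except Exception as exc:
        raise StageError("report", exc) from exc

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest["outputs"] = {
        name: {"path": str(p), "sha256": _sha256(p)} for name, p in outputs.items()
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return RunResult(out, catalog, psi["cond1"], psi["cond2"], calls, summary, manifest, outputs)
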