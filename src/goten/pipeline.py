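"""End-to-end orchestration: tag -> call -> genotype -> enrich -> report.

The stage functions in the other modules stay pure; this module wires them
together over in-memory objects (for tests and simulations) or files (for
the command line), and keeps per-stage record counts so that every input
read is accounted for (out + rejected == in).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from . import __version__
from .alleles import call_alleles
from .enrichment import UNANNOTATED, case_summary, enrichment_test, tabulate_genotypes
from .genotyper import (
    GenotypeModel,
    build_consensuses,
    consensus_frame,
    genotype_cells,
)
from .io import VariantTarget, Whitelist, write_table
from .tagging import TagExtractionConfig, tag_reads


@dataclass
class PipelineResult:
    """Everything one pipeline run produced, with conservation statistics."""

    tagged_count: int
    rejections: dict
    observations: pd.DataFrame
    consensuses: pd.DataFrame
    genotypes: pd.DataFrame
    tabulation: pd.DataFrame
    enrichment: pd.DataFrame
    summary: dict
    stats: dict = field(default_factory=dict)


def run_cohort(
    reads: Iterable,
    whitelist: Whitelist,
    target: VariantTarget,
    tags: Optional[pd.DataFrame] = None,
    annotation: Optional[pd.DataFrame] = None,
    *,
    tag_cfg: Optional[TagExtractionConfig] = None,
    model: Optional[GenotypeModel] = None,
) -> PipelineResult:
    """Run the full pipeline over in-memory inputs."""
    tag_cfg = tag_cfg or TagExtractionConfig()
    model = model or GenotypeModel()
    reads = list(reads)
    tagged, rejections = tag_reads(reads, tag_cfg, whitelist)
    observations = call_alleles(tagged, target)
    consensuses = build_consensuses(
        (o for o in _obs_iter(observations)), epsilon_floor=model.epsilon_floor
    )
    genotypes = genotype_cells(consensuses, model, tags=tags, gene=target.gene)
    if annotation is not None:
        tabulation = tabulate_genotypes(genotypes, annotation)
        # unannotated cells are tabulated but form no cell type to test
        enr_input = tabulation.loc[tabulation["cell_type"] != UNANNOTATED].rename(
            columns={"n_mut": "k_mut"}
        )
        enrichment = enrichment_test(enr_input) if not enr_input.empty else pd.DataFrame()
    else:
        tabulation = pd.DataFrame()
        enrichment = pd.DataFrame()
    summary = case_summary(genotypes) if len(genotypes) else {
        "n_cells": 0, "n_genotyped": 0, "n_ref": 0, "n_mut": 0,
        "mut_fraction_pct": float("nan"),
    }
    n_reads = len(reads)
    stats = {
        "n_reads_in": n_reads,
        "n_tagged": len(tagged),
        "n_rejected": int(sum(rejections.values())),
        "n_barcodes_tagged": int(observations["cbc"].nunique()) if len(observations) else 0,
        "genotyping_rate_vs_tagged_barcodes": (
            summary["n_genotyped"] / observations["cbc"].nunique()
            if len(observations) and observations["cbc"].nunique()
            else float("nan")
        ),
        "genotyping_rate_vs_annotated_cells": (
            summary["n_genotyped"] / len(annotation)
            if annotation is not None and len(annotation)
            else float("nan")
        ),
    }
    assert stats["n_tagged"] + stats["n_rejected"] == n_reads
    return PipelineResult(
        tagged_count=len(tagged),
        rejections=dict(rejections),
        observations=observations,
        consensuses=consensus_frame(consensuses),
        genotypes=genotypes,
        tabulation=tabulation,
        enrichment=enrichment,
        summary=summary,
        stats=stats,
    )


def _obs_iter(frame: pd.DataFrame):
    from .genotyper import observations_from_frame

    return observations_from_frame(frame)


def write_manifest(
    path: str | Path,
    *,
    stages: dict,
    config: dict,
    seed: Optional[int] = None,
) -> None:
    """Write the machine-readable run manifest (JSON)."""
    manifest = {
        "tool_version": __version__,
        "seed": seed,
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "stages": stages,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_result(result: PipelineResult, outdir: str | Path) -> dict:
    """Write every pipeline table under ``outdir``; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    def _emit(name: str, frame: pd.DataFrame):
        p = outdir / f"{name}.tsv"
        write_table(frame, p)
        paths[name] = str(p)

    _emit("alleles", result.observations)
    _emit("consensuses", result.consensuses)
    _emit("genotypes", result.genotypes)
    if len(result.tabulation):
        _emit("tabulation", result.tabulation)
    if len(result.enrichment):
        _emit("enrichment", result.enrichment)
    rej = pd.DataFrame(
        sorted(result.rejections.items()), columns=["reason", "count"]
    )
    _emit("rejections", rej)
    with open(outdir / "summary.json", "w") as fh:
        json.dump({**result.summary, **result.stats}, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["summary"] = str(outdir / "summary.json")
    return paths
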