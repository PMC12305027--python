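"""Ground-truth simulator for every pipeline input.

Emulates a mosaic nuclear population profiled with droplet snRNA-seq and a
targeted long-read amplicon library over the same cDNA: each cell draws a
type and a genotype (het-mut with probability ``mosaic_fraction``; for a
heterozygous somatic SNV the bulk VAF is about mosaic_fraction / 2), each
captured transcript gets a unique UMI and an allele (alt with probability
``beta_true`` in het cells), and each transcript is amplified into a
geometric number of noisy long reads built as
anchor + cell barcode + UMI + amplicon payload.  Substitution and indel
errors are position-independent; base qualities are drawn around the Phred
equivalent of the substitution rate so consensus arithmetic is calibrated.
The short-read tag table contains each true (cbc, umi, gene) triple,
optionally thinned by a capture probability, and the whitelist is the true
barcode set plus 10x decoy barcodes to exercise correction.

A fixed seed makes every output byte-identical between runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .io import (
    FastqRead,
    VariantTarget,
    Whitelist,
    write_fastq,
    write_table,
    write_targets,
    write_whitelist,
)
from .tagging import DEFAULT_ANCHOR, reverse_complement

_BASES = np.array(list("ACGT"))

TRUTH_CELL_COLUMNS = ["cbc", "cell_type", "true_genotype"]
TRUTH_READ_COLUMNS = ["read_id", "cbc", "umi", "allele"]

DEFAULT_CELL_TYPE_PROBS = {
    "ExN": 0.45,
    "InN": 0.20,
    "Astro": 0.15,
    "Oligo": 0.12,
    "Micro": 0.08,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated cohort.

    ``expression_rate`` (mean on-target transcripts per cell, Poisson) may
    be a single number or a per-cell-type mapping.  ``reads_per_umi`` is the
    mean of a geometric (min 1) amplification depth.  Error rates are
    per-base probabilities.
    """

    n_cells: int = 500
    mosaic_fraction: float = 0.30
    cell_type_probs: dict = field(default_factory=lambda: dict(DEFAULT_CELL_TYPE_PROBS))
    expression_rate: Union[float, dict] = 6.0
    reads_per_umi: float = 3.0
    seq_error_rate: float = 0.02
    indel_rate: float = 0.01
    beta_true: float = 0.5
    umi_len: int = 12
    cbc_len: int = 16
    capture_prob: float = 1.0
    decoy_factor: int = 10
    anchor_seq: str = DEFAULT_ANCHOR
    target: Optional[VariantTarget] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.mosaic_fraction <= 1:
            raise ValueError("mosaic_fraction must be in [0, 1]")
        if not 0 < self.beta_true < 1:
            raise ValueError("beta_true must be in (0, 1)")
        if self.seq_error_rate < 0 or self.indel_rate < 0:
            raise ValueError("error rates must be >= 0")
        total = sum(self.cell_type_probs.values())
        if not math.isclose(total, 1.0, rel_tol=1e-9):
            raise ValueError(f"cell_type_probs must sum to 1, got {total}")

    def rate_for(self, cell_type: str) -> float:
        if isinstance(self.expression_rate, dict):
            return float(self.expression_rate[cell_type])
        return float(self.expression_rate)


@dataclass
class SimulatedCohort:
    """All five pipeline inputs plus the generating truth."""

    reads: list
    whitelist: Whitelist
    tags: pd.DataFrame
    annotation: pd.DataFrame
    truth_cells: pd.DataFrame
    truth_reads: pd.DataFrame
    target: VariantTarget
    config: SimulationConfig

    def write(self, outdir: str | Path) -> dict:
        """Write the standard input files plus truth tables; returns paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fastq": outdir / "reads.fastq.gz",
            "whitelist": outdir / "whitelist.txt",
            "tags": outdir / "tags.tsv",
            "annotation": outdir / "cells.tsv",
            "targets": outdir / "targets.yaml",
            "truth_cells": outdir / "truth_cells.tsv",
            "truth_reads": outdir / "truth_reads.tsv",
        }
        write_fastq(self.reads, paths["fastq"])
        write_whitelist(self.whitelist, paths["whitelist"])
        write_table(self.tags, paths["tags"])
        write_table(self.annotation, paths["annotation"])
        write_targets([self.target], paths["targets"])
        write_table(self.truth_cells, paths["truth_cells"])
        write_table(self.truth_reads, paths["truth_reads"])
        return {k: str(v) for k, v in paths.items()}


def random_target(
    rng: np.random.Generator,
    *,
    gene: str = "MTOR",
    amplicon_len: int = 500,
    variant_offset: int = 250,
    variant_id: str = "sim_variant",
) -> VariantTarget:
    """A random amplicon with an SNV at ``variant_offset`` (default mid-amplicon)."""
    ref = "".join(rng.choice(_BASES, size=amplicon_len))
    ref_allele = ref[variant_offset]
    alt_allele = str(rng.choice([b for b in "ACGT" if b != ref_allele]))
    return VariantTarget(variant_id, gene, ref, variant_offset, ref_allele, alt_allele)


def _unique_kmers(rng: np.random.Generator, n: int, k: int, exclude: set[str]) -> list[str]:
    out: list[str] = []
    seen = set(exclude)
    while len(out) < n:
        kmer = "".join(rng.choice(_BASES, size=k))
        if kmer not in seen:
            seen.add(kmer)
            out.append(kmer)
    return out


_BASE_TO_IDX = np.full(128, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_TO_IDX[ord(_b)] = _i


def _noisy_copy(
    rng: np.random.Generator, template: str, sub_rate: float, indel_rate: float
) -> tuple[str, np.ndarray]:
    """One sequencing copy of ``template`` with per-base qualities."""
    q0 = int(round(-10.0 * math.log10(sub_rate))) if sub_rate > 0 else 40
    idx = _BASE_TO_IDX[np.frombuffer(template.encode("ascii"), dtype=np.uint8)].astype(np.int64)
    if indel_rate > 0:
        r = rng.random(idx.size)
        keep = r >= indel_rate / 2.0  # deletion with prob indel_rate/2
        # insertion before the base with prob indel_rate/2
        ins_before = np.flatnonzero((r >= indel_rate / 2.0) & (r < indel_rate))
        kept_before = np.cumsum(keep) - keep  # kept elements strictly before i
        positions = kept_before[ins_before]
        idx = idx[keep]
        if positions.size:
            idx = np.insert(idx, positions, rng.integers(0, 4, size=positions.size))
    n = idx.size
    quals = np.clip(q0 + rng.integers(-2, 3, size=n), 2, 41).astype(np.int16)
    if sub_rate > 0:
        subs = rng.random(n) < sub_rate
        if subs.any():
            shift = rng.integers(1, 4, size=int(subs.sum()))
            idx[subs] = (idx[subs] + shift) % 4
    seq = "".join(_BASES[idx])
    return seq, quals


def simulate_cohort(cfg: SimulationConfig) -> SimulatedCohort:
    """Draw a full cohort: cells, transcripts, tag table and noisy reads."""
    rng = np.random.default_rng(cfg.seed)
    target = cfg.target if cfg.target is not None else random_target(rng)

    types = list(cfg.cell_type_probs)
    type_probs = np.array([cfg.cell_type_probs[t] for t in types])
    barcodes = _unique_kmers(rng, cfg.n_cells, cfg.cbc_len, set())
    decoys = _unique_kmers(rng, cfg.decoy_factor * cfg.n_cells, cfg.cbc_len, set(barcodes))

    amplicon_ref = target.amplicon_ref
    amplicon_alt = (
        amplicon_ref[: target.variant_offset]
        + target.alt_allele
        + amplicon_ref[target.variant_offset + 1 :]
    )

    truth_cells = []
    truth_reads = []
    tag_rows = []
    reads: list[FastqRead] = []
    read_no = 0
    for cbc in barcodes:
        cell_type = types[rng.choice(len(types), p=type_probs)]
        is_het = bool(rng.random() < cfg.mosaic_fraction)
        truth_cells.append((cbc, cell_type, "het-mut" if is_het else "ref-hom"))
        n_transcripts = rng.poisson(cfg.rate_for(cell_type))
        if n_transcripts == 0:
            continue
        umis = _unique_kmers(rng, n_transcripts, cfg.umi_len, set())
        for umi in umis:
            allele = "alt" if (is_het and rng.random() < cfg.beta_true) else "ref"
            tag_rows.append((cbc, umi, target.gene, 1))
            template = cfg.anchor_seq + cbc + umi + (
                amplicon_alt if allele == "alt" else amplicon_ref
            )
            if cfg.reads_per_umi > 1.0:
                n_copies = int(rng.geometric(1.0 / cfg.reads_per_umi))
            else:
                n_copies = 1
            for _ in range(n_copies):
                seq, qual = _noisy_copy(rng, template, cfg.seq_error_rate, cfg.indel_rate)
                if rng.random() < 0.5:
                    seq, qual = reverse_complement(seq), qual[::-1]
                read_id = f"sim_{read_no:07d}"
                read_no += 1
                reads.append(FastqRead(read_id, seq, qual))
                truth_reads.append((read_id, cbc, umi, allele))

    tags = pd.DataFrame(tag_rows, columns=["cbc", "umi", "gene", "count"])
    if cfg.capture_prob < 1.0:
        tags = downsample_tags(tags, cfg.capture_prob, rng=rng)
    annotation = pd.DataFrame(
        [(cbc, ct) for cbc, ct, _ in truth_cells], columns=["cbc", "cell_type"]
    )
    return SimulatedCohort(
        reads=reads,
        whitelist=Whitelist(frozenset(barcodes) | frozenset(decoys)),
        tags=tags,
        annotation=annotation,
        truth_cells=pd.DataFrame(truth_cells, columns=TRUTH_CELL_COLUMNS),
        truth_reads=pd.DataFrame(truth_reads, columns=TRUTH_READ_COLUMNS),
        target=target,
        config=cfg,
    )


def downsample_tags(
    tags: pd.DataFrame,
    capture_prob: float,
    *,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Retain each tag row independently with probability ``capture_prob``."""
    if not 0 <= capture_prob <= 1:
        raise ValueError("capture_prob must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    if capture_prob == 1.0:
        return tags.copy()
    keep = rng.random(len(tags)) < capture_prob
    return tags.loc[keep].reset_index(drop=True)


def simulate_genotyping_efficiency(
    n_cells: int,
    *,
    slope: float = 1.0,
    intercept: float = -1.0,
    type_effects: Optional[dict] = None,
    cell_type_probs: Optional[dict] = None,
    expression_mean: float = 5.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cell covariate table with a known genotyping-probability model.

    Genotyping success is Bernoulli with logit = intercept +
    slope * log1p(expression) + type effect; expression is Poisson with mean
    ``expression_mean``.  Used to validate the efficiency QC regression.
    """
    rng = np.random.default_rng(seed)
    probs = cell_type_probs or DEFAULT_CELL_TYPE_PROBS
    types = list(probs)
    p = np.array([probs[t] for t in types])
    effects = type_effects or {}
    cell_types = rng.choice(types, size=n_cells, p=p)
    expression = rng.poisson(expression_mean, size=n_cells)
    x = np.log1p(expression)
    eta = intercept + slope * x + np.array([effects.get(t, 0.0) for t in cell_types])
    genotyped = rng.random(n_cells) < 1.0 / (1.0 + np.exp(-eta))
    return pd.DataFrame(
        {
            "cbc": [f"cell_{i:05d}" for i in range(n_cells)],
            "cell_type": cell_types,
            "log1p_expression": x,
            "genotyped": genotyped,
        }
    )
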