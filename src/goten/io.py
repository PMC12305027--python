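"""Readers and writers for the external formats the pipeline touches.

Every other module consumes and emits the types defined here: variant
targets, FASTQ reads, cell-barcode whitelists, short-read (cbc, umi, gene)
tag tables and cell-type annotations.  Tabular data is held in pandas
DataFrames with documented column schemas; single records are dataclasses.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
import pysam
import yaml

VALID_BASES = frozenset("ACGT")

#: columns of an Illumina tag table
TAG_COLUMNS = ["cbc", "umi", "gene", "count"]

#: columns of a cell annotation table
ANNOTATION_COLUMNS = ["cbc", "cell_type"]

_CB_SUFFIX = re.compile(r"-\d+$")


class FormatError(ValueError):
    """A malformed input file or record."""


@dataclass(frozen=True)
class VariantTarget:
    """One targeted somatic SNV within a PCR amplicon.

    ``variant_offset`` is 0-based within ``amplicon_ref``.  Genomic
    coordinates in user configuration are 1-based and converted on load.
    """

    variant_id: str
    gene: str
    amplicon_ref: str
    variant_offset: int
    ref_allele: str
    alt_allele: str
    genomic_label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "amplicon_ref", self.amplicon_ref.upper())
        if not set(self.amplicon_ref) <= VALID_BASES:
            raise ValueError(f"{self.variant_id}: amplicon_ref contains non-ACGT bases")
        if not 0 <= self.variant_offset < len(self.amplicon_ref):
            raise ValueError(
                f"{self.variant_id}: variant_offset {self.variant_offset} outside "
                f"amplicon of length {len(self.amplicon_ref)}"
            )
        for name in ("ref_allele", "alt_allele"):
            allele = getattr(self, name)
            if allele not in VALID_BASES:
                raise ValueError(f"{self.variant_id}: {name} {allele!r} not a single ACGT base")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.variant_id}: ref and alt alleles are identical")
        if self.amplicon_ref[self.variant_offset] != self.ref_allele:
            raise ValueError(
                f"{self.variant_id}: amplicon_ref[{self.variant_offset}] is "
                f"{self.amplicon_ref[self.variant_offset]!r}, expected ref allele "
                f"{self.ref_allele!r}"
            )


@dataclass(frozen=True)
class Whitelist:
    """The universe of valid cell barcodes (all the same length)."""

    barcodes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.barcodes:
            raise ValueError("whitelist is empty")
        lengths = {len(b) for b in self.barcodes}
        if len(lengths) != 1:
            raise ValueError(f"whitelist barcodes have mixed lengths {sorted(lengths)}")
        for b in self.barcodes:
            if not set(b) <= VALID_BASES:
                raise ValueError(f"whitelist barcode {b!r} contains non-ACGT characters")

    @property
    def barcode_length(self) -> int:
        return len(next(iter(self.barcodes)))

    def __contains__(self, barcode: str) -> bool:
        return barcode in self.barcodes

    def __len__(self) -> int:
        return len(self.barcodes)


@dataclass
class FastqRead:
    """A sequencing read with Phred-scaled base qualities (Phred+33 on disk)."""

    read_id: str
    sequence: str
    qualities: np.ndarray  # integer Phred scores, same length as sequence

    def __post_init__(self) -> None:
        self.qualities = np.asarray(self.qualities, dtype=np.int16)
        if len(self.sequence) != len(self.qualities):
            raise FormatError(
                f"record {self.read_id!r}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )


def read_fastq(path: str | Path) -> Iterator[FastqRead]:
    """Stream reads from a FASTQ file (optionally gzip-compressed).

    Sequences are uppercased and qualities decoded from Phred+33.  A record
    whose sequence and quality strings differ in length raises
    :class:`FormatError` naming the record.
    """
    n = 0
    with pysam.FastxFile(str(path)) as fh:
        iterator = iter(fh)
        while True:
            try:
                entry = next(iterator)
            except StopIteration:
                break
            except ValueError as exc:  # htslib: truncated/mismatched record
                raise FormatError(f"{path}: malformed FASTQ record {n + 1}: {exc}") from exc
            if entry.quality is None:
                raise FormatError(f"record {entry.name!r}: missing quality string (FASTA?)")
            seq = entry.sequence.upper()
            qual = np.frombuffer(entry.quality.encode("ascii"), dtype=np.uint8).astype(np.int16) - 33
            if len(seq) != len(qual):
                raise FormatError(
                    f"record {entry.name!r}: sequence length {len(seq)} != "
                    f"quality length {len(qual)}"
                )
            n += 1
            yield FastqRead(entry.name, seq, qual)


def write_fastq(reads: Iterable[FastqRead], path: str | Path) -> None:
    """Write reads as Phred+33 FASTQ; gzip-compressed when path ends in .gz."""
    path = Path(path)
    import gzip

    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for read in reads:
            qual = "".join(chr(int(q) + 33) for q in read.qualities)
            fh.write(f"@{read.read_id}\n{read.sequence}\n+\n{qual}\n")


def load_whitelist(path: str | Path) -> Whitelist:
    """Load a one-barcode-per-line whitelist."""
    barcodes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                barcodes.append(line.upper())
    if len(barcodes) != len(set(barcodes)):
        raise FormatError(f"{path}: whitelist contains duplicate barcodes")
    return Whitelist(frozenset(barcodes))


def write_whitelist(whitelist: Whitelist, path: str | Path) -> None:
    with open(path, "w") as fh:
        for barcode in sorted(whitelist.barcodes):
            fh.write(barcode + "\n")


def strip_gem_suffix(barcode: str) -> str:
    """Strip the 10X GEM-well suffix (e.g. ``-1``) from a corrected barcode."""
    return _CB_SUFFIX.sub("", barcode)


def load_illumina_tags(
    path: str | Path,
    genes: Iterable[str],
    *,
    cb_tag: str = "CB",
    umi_tag: str = "UB",
    gene_tag: str = "GX",
) -> pd.DataFrame:
    """Load the short-read (cbc, umi, gene) evidence for the target genes.

    ``path`` is either a coordinate-sorted BAM carrying corrected-barcode /
    UMI / gene tags in the standard 10X dialect (CB/UB/GX; CB suffixes such
    as ``-1`` are stripped) or a TSV with header ``cbc, umi, gene`` and an
    optional ``count`` column.  Duplicate (cbc, umi, gene) triples are
    collapsed with summed counts; only rows for ``genes`` are kept.
    """
    genes = set(genes)
    path = Path(path)
    if path.suffix == ".bam":
        rows = _tags_from_bam(path, genes, cb_tag, umi_tag, gene_tag)
    else:
        rows = _tags_from_tsv(path, genes)
    if rows.empty:
        table = pd.DataFrame(columns=TAG_COLUMNS).astype({"count": np.int64})
    else:
        table = (
            rows.groupby(["cbc", "umi", "gene"], as_index=False)["count"]
            .sum()
            .sort_values(["cbc", "umi", "gene"], ignore_index=True)
        )
    seen = set(table["gene"])
    for gene in sorted(genes - seen):
        warnings.warn(f"no tag rows found for requested gene {gene!r}", stacklevel=2)
    return table[TAG_COLUMNS]


def _tags_from_bam(path: Path, genes: set[str], cb_tag: str, umi_tag: str, gene_tag: str) -> pd.DataFrame:
    records = []
    n_alignments = 0
    n_tagged = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as bam:
        for aln in bam.fetch(until_eof=True):
            n_alignments += 1
            if not (aln.has_tag(cb_tag) and aln.has_tag(umi_tag) and aln.has_tag(gene_tag)):
                continue
            n_tagged += 1
            gene = aln.get_tag(gene_tag)
            if gene not in genes:
                continue
            cbc = strip_gem_suffix(aln.get_tag(cb_tag))
            records.append((cbc, aln.get_tag(umi_tag), gene, 1))
    if n_alignments > 0 and n_tagged == 0:
        raise FormatError(
            f"{path}: no alignment carries the {cb_tag}/{umi_tag}/{gene_tag} tags"
        )
    return pd.DataFrame(records, columns=TAG_COLUMNS)


def _tags_from_tsv(path: Path, genes: set[str]) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype=str)
    required = {"cbc", "umi", "gene"}
    if not required <= set(table.columns):
        raise FormatError(f"{path}: tag table must have columns {sorted(required)}")
    if "count" in table.columns:
        table["count"] = table["count"].astype(np.int64)
    else:
        table["count"] = 1
    table["cbc"] = table["cbc"].map(strip_gem_suffix)
    return table.loc[table["gene"].isin(genes), TAG_COLUMNS]


def load_cell_annotation(path: str | Path) -> pd.DataFrame:
    """Load a barcode → cell-type annotation (TSV or CSV by extension)."""
    sep = "," if str(path).endswith(".csv") else "\t"
    table = pd.read_csv(path, sep=sep, dtype=str)
    if not set(ANNOTATION_COLUMNS) <= set(table.columns):
        raise FormatError(f"{path}: annotation must have columns {ANNOTATION_COLUMNS}")
    table = table[ANNOTATION_COLUMNS]
    if table["cbc"].duplicated().any():
        dup = table.loc[table["cbc"].duplicated(), "cbc"].iloc[0]
        raise FormatError(f"{path}: barcode {dup!r} annotated more than once")
    return table


def load_targets(path: str | Path) -> list[VariantTarget]:
    """Load variant targets from a YAML file.

    The file holds a list (or a ``targets:`` list) of mappings with keys
    ``variant_id, gene, amplicon_ref, ref_allele, alt_allele`` and either
    ``variant_offset`` (0-based) or ``variant_position`` (1-based, VCF-style,
    converted on load).
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if isinstance(doc, dict):
        doc = doc.get("targets", [doc])
    targets = []
    for entry in doc:
        entry = dict(entry)
        if "variant_offset" not in entry:
            if "variant_position" not in entry:
                raise FormatError(
                    f"target {entry.get('variant_id')!r}: needs variant_offset (0-based) "
                    "or variant_position (1-based)"
                )
            entry["variant_offset"] = int(entry.pop("variant_position")) - 1
        entry.pop("variant_position", None)
        targets.append(
            VariantTarget(
                variant_id=str(entry["variant_id"]),
                gene=str(entry["gene"]),
                amplicon_ref=str(entry["amplicon_ref"]),
                variant_offset=int(entry["variant_offset"]),
                ref_allele=str(entry["ref_allele"]).upper(),
                alt_allele=str(entry["alt_allele"]).upper(),
                genomic_label=str(entry.get("genomic_label", "")),
            )
        )
    return targets


def write_targets(targets: Iterable[VariantTarget], path: str | Path) -> None:
    doc = [
        {
            "variant_id": t.variant_id,
            "gene": t.gene,
            "amplicon_ref": t.amplicon_ref,
            "variant_offset": t.variant_offset,
            "ref_allele": t.ref_allele,
            "alt_allele": t.alt_allele,
            "genomic_label": t.genomic_label,
        }
        for t in targets
    ]
    with open(path, "w") as fh:
        yaml.safe_dump({"targets": doc}, fh, sort_keys=False)


def write_table(table: pd.DataFrame, path: str | Path, *, sort_by: list[str] | None = None) -> None:
    """Write a table as sorted, tab-separated UTF-8 with NaN rendered as NA.

    Rows are sorted by ``sort_by`` (default: all columns left to right) so
    repeated runs produce bit-identical files.
    """
    keys = sort_by if sort_by is not None else list(table.columns)
    out = table.sort_values(keys, ignore_index=True) if len(table) and keys else table
    out.to_csv(path, sep="\t", index=False, na_rep="NA", encoding="utf-8")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a table written by :func:`write_table` (NA → NaN)."""
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=True)
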