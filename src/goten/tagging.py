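"""Barcode/UMI extraction from noisy long amplicon reads.

Long-read amplicons start (in one orientation) with the constant 10X
partial-R1 sequence, followed by the 16-nt cell barcode, the 12-nt UMI and
the amplicon payload.  The anchor is located by bounded semi-global edit
distance on both strands, the barcode is corrected against the short-read
whitelist by Levenshtein distance, and the payload downstream of the UMI is
carried forward for allele calling.

Edit (Levenshtein) distance, not Hamming, is used for both the anchor and
the barcode: nanopore errors are indel-dominated.  Base qualities are not
used during correction; nanopore quality strings are poorly calibrated at
the single-barcode scale.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional

import edlib
import numpy as np

from .io import FastqRead, Whitelist

#: constant sequence immediately 5' of the cell barcode (10X partial R1)
DEFAULT_ANCHOR = "CTACACGACGCTCTTCCGATCT"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

REJECTION_REASONS = ("no-anchor", "cbc-unmatched", "cbc-ambiguous", "too-short")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TagExtractionConfig:
    """Parameters of the anchor search and barcode correction."""

    anchor_seq: str = DEFAULT_ANCHOR
    max_anchor_mismatch_frac: float = 0.15  # of anchor length, edit distance
    cbc_len: int = 16
    umi_len: int = 12
    max_cbc_edits: int = 1
    both_strands: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.max_anchor_mismatch_frac < 0.5:
            raise ValueError("max_anchor_mismatch_frac must be in [0, 0.5)")
        if self.cbc_len <= 0 or self.umi_len <= 0:
            raise ValueError("cbc_len and umi_len must be positive")

    @property
    def max_anchor_edits(self) -> int:
        return math.ceil(self.max_anchor_mismatch_frac * len(self.anchor_seq))


@dataclass
class TaggedRead:
    """A long read with its barcode/UMI cassette resolved.

    ``payload_seq``/``payload_qual`` hold the remainder of the read
    downstream of the UMI, in the orientation in which the anchor was found.
    """

    read_id: str
    cbc_raw: str
    cbc: Optional[str]
    umi: str
    strand: str  # '+' or '-'
    anchor_edits: int
    cbc_edits: Optional[int]
    payload_seq: str
    payload_qual: np.ndarray


@dataclass(frozen=True)
class Rejection:
    read_id: str
    reason: str


@dataclass(frozen=True)
class AnchorHit:
    strand: str
    end: int  # 0-based position just past the anchor, in hit orientation
    edits: int


def find_anchor(sequence: str, cfg: TagExtractionConfig) -> Optional[AnchorHit]:
    """Best bounded-edit-distance hit of the anchor on either strand.

    The anchor is searched semi-globally (infix) in the read and, when
    ``both_strands``, in its reverse complement; a hit is accepted iff its
    edit distance is at most ``ceil(max_anchor_mismatch_frac * len(anchor))``.
    Equal-distance hits on both strands break toward '+'.
    """
    k = cfg.max_anchor_edits
    hits = []
    strands = ("+", "-") if cfg.both_strands else ("+",)
    for strand in strands:
        oriented = sequence if strand == "+" else reverse_complement(sequence)
        res = edlib.align(cfg.anchor_seq, oriented, mode="HW", task="locations", k=k)
        if res["editDistance"] >= 0:
            end = res["locations"][0][1] + 1  # inclusive end -> exclusive
            hits.append(AnchorHit(strand, end, res["editDistance"]))
    if not hits:
        return None
    # stable: '+' listed first, so min() breaks distance ties toward '+'
    return min(hits, key=lambda h: h.edits)


class BarcodeCorrector:
    """Correct raw barcodes against a whitelist by Levenshtein distance.

    An exact match always wins.  Otherwise the unique whitelist entry within
    ``max_edits`` is returned; two or more entries tying at the minimal
    distance give an ambiguous result.  For the common case of
    equal-length barcodes and ``max_edits == 1``, Levenshtein-1 coincides
    with Hamming-1, so correction is a substitution-neighborhood dictionary
    lookup; larger radii fall back to a bounded scan of the whitelist.
    """

    def __init__(self, whitelist: Whitelist, max_edits: int = 1):
        self.whitelist = whitelist
        self.max_edits = max_edits
        self._members = whitelist.barcodes
        self._length = whitelist.barcode_length

    def correct(self, cbc_raw: str) -> tuple[Optional[str], Optional[str], Optional[int]]:
        """Return (barcode, failure_reason, edits); reason is None on success."""
        if cbc_raw in self._members:
            return cbc_raw, None, 0
        if self.max_edits == 0:
            return None, "cbc-unmatched", None
        if self.max_edits == 1 and len(cbc_raw) == self._length:
            return self._correct_hamming1(cbc_raw)
        return self._correct_scan(cbc_raw)

    def _correct_hamming1(self, cbc_raw: str):
        matches = []
        for i, base in enumerate(cbc_raw):
            for sub in "ACGT":
                if sub == base:
                    continue
                neighbor = cbc_raw[:i] + sub + cbc_raw[i + 1 :]
                if neighbor in self._members:
                    matches.append(neighbor)
        if len(matches) == 1:
            return matches[0], None, 1
        if matches:
            return None, "cbc-ambiguous", None
        return None, "cbc-unmatched", None

    def _correct_scan(self, cbc_raw: str):
        best_dist = self.max_edits + 1
        best: list[str] = []
        for member in self._members:
            res = edlib.align(cbc_raw, member, mode="NW", task="distance", k=best_dist)
            d = res["editDistance"]
            if d < 0:
                continue
            if d < best_dist:
                best_dist, best = d, [member]
            elif d == best_dist:
                best.append(member)
        if len(best) == 1:
            return best[0], None, best_dist
        if best:
            return None, "cbc-ambiguous", None
        return None, "cbc-unmatched", None


def correct_barcode(
    cbc_raw: str, whitelist: Whitelist, max_cbc_edits: int = 1
) -> tuple[Optional[str], Optional[str], Optional[int]]:
    """One-shot barcode correction; see :class:`BarcodeCorrector`.

    Returns ``(barcode, failure_reason, edits)`` where ``failure_reason``
    is None on success and ``cbc-unmatched``/``cbc-ambiguous`` otherwise.
    """
    return BarcodeCorrector(whitelist, max_cbc_edits).correct(cbc_raw)


def extract_tags(
    read: FastqRead, cfg: TagExtractionConfig, corrector: BarcodeCorrector
) -> TaggedRead | Rejection:
    """Resolve a read's barcode/UMI cassette, or reject it with a reason.

    Rejection reasons: ``too-short`` (read cannot hold anchor + cassette, or
    the cassette runs off the read end), ``no-anchor``, ``cbc-unmatched``,
    ``cbc-ambiguous``.
    """
    min_len = len(cfg.anchor_seq) + cfg.cbc_len + cfg.umi_len
    if len(read.sequence) <= min_len:
        return Rejection(read.read_id, "too-short")
    hit = find_anchor(read.sequence, cfg)
    if hit is None:
        return Rejection(read.read_id, "no-anchor")
    if hit.strand == "+":
        seq, qual = read.sequence, read.qualities
    else:
        seq, qual = reverse_complement(read.sequence), read.qualities[::-1]
    cassette_end = hit.end + cfg.cbc_len + cfg.umi_len
    if cassette_end > len(seq):
        return Rejection(read.read_id, "too-short")
    cbc_raw = seq[hit.end : hit.end + cfg.cbc_len]
    umi = seq[hit.end + cfg.cbc_len : cassette_end]
    cbc, reason, cbc_edits = corrector.correct(cbc_raw)
    if cbc is None:
        return Rejection(read.read_id, reason)
    return TaggedRead(
        read_id=read.read_id,
        cbc_raw=cbc_raw,
        cbc=cbc,
        umi=umi,
        strand=hit.strand,
        anchor_edits=hit.edits,
        cbc_edits=cbc_edits,
        payload_seq=seq[cassette_end:],
        payload_qual=np.asarray(qual[cassette_end:]),
    )


def tag_reads(
    reads: Iterable[FastqRead],
    cfg: TagExtractionConfig,
    whitelist: Whitelist,
) -> tuple[list[TaggedRead], Counter]:
    """Tag a stream of reads; returns tagged reads and rejection counts."""
    corrector = BarcodeCorrector(whitelist, cfg.max_cbc_edits)
    tagged: list[TaggedRead] = []
    rejections: Counter = Counter()
    for read in reads:
        result = extract_tags(read, cfg, corrector)
        if isinstance(result, Rejection):
            rejections[result.reason] += 1
        else:
            tagged.append(result)
    return tagged, rejections
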