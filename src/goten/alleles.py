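"""Anchor tagged-read payloads to the amplicon reference and read out the
allele at the variant position.

The payload is aligned semi-globally to the amplicon reference (payload end
overhangs are free); the alignment is accepted when its identity over the
reference span actually covered by payload bases is at least
``min_identity`` and that span covers a window around the variant.  The
variant-column base and its FASTQ quality become an allele observation:
``ref``/``alt`` when the base equals the respective allele, ``other`` for a
third base, ``missing`` when the column is deleted or the read does not
align/cover it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Optional

import edlib
import numpy as np
import pandas as pd

from .io import VariantTarget
from .tagging import TaggedRead

_CIGAR_TOKEN = re.compile(r"(\d+)([=XID])")

#: minimum payload length worth aligning
MIN_PAYLOAD_LEN = 30

#: default acceptance thresholds for payload-to-amplicon alignment
DEFAULT_MIN_IDENTITY = 0.75
DEFAULT_FLANK = 15

OBSERVATION_COLUMNS = [
    "read_id", "cbc", "umi", "strand", "allele", "base_quality", "alignment_edits",
]


@dataclass
class PayloadAlignment:
    """Per-column mapping of the amplicon reference onto a payload.

    ``ref_to_payload[i]`` is the payload index aligned to reference position
    ``i``, or -1 when that reference base is deleted from (or not covered
    by) the payload.
    """

    ref_to_payload: np.ndarray
    edits: int
    identity: float
    ref_start: int  # first reference position covered by a payload base
    ref_end: int    # last reference position covered (inclusive)


@dataclass
class AlleleObservation:
    read_id: str
    cbc: str
    umi: str
    strand: str
    allele: str  # ref | alt | other | missing
    base_quality: Optional[int]  # None iff allele == missing
    alignment_edits: Optional[int]  # None when the payload did not align


def align_payload(
    payload: str,
    target: VariantTarget,
    *,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    flank: int = DEFAULT_FLANK,
) -> Optional[PayloadAlignment]:
    """Semi-global alignment of a payload to the amplicon reference.

    Returns None (unaligned) when the payload is too short, the identity
    over the covered span falls below ``min_identity``, or the span fails to
    cover ``variant_offset ± flank`` (clamped to the amplicon bounds).
    """
    ref = target.amplicon_ref
    if len(payload) < MIN_PAYLOAD_LEN:
        return None
    res = edlib.align(ref, payload, mode="HW", task="path")
    if res["editDistance"] < 0 or res["cigar"] is None:
        return None

    ref_to_payload = np.full(len(ref), -1, dtype=np.int64)
    ref_pos = 0
    pay_pos = res["locations"][0][0]
    columns = []  # (ref_pos or -1, is_match) per alignment column
    for count, op in _CIGAR_TOKEN.findall(res["cigar"]):
        n = int(count)
        if op == "=" or op == "X":
            ref_to_payload[ref_pos : ref_pos + n] = np.arange(pay_pos, pay_pos + n)
            columns.extend((ref_pos + i, op == "=") for i in range(n))
            ref_pos += n
            pay_pos += n
        elif op == "I":  # consumes reference only: deletion in payload
            columns.extend((ref_pos + i, False) for i in range(n))
            ref_pos += n
        else:  # 'D' consumes payload only: insertion relative to reference
            columns.append((-1, False))
            pay_pos += n

    covered = np.flatnonzero(ref_to_payload >= 0)
    if covered.size == 0:
        return None
    ref_start, ref_end = int(covered[0]), int(covered[-1])

    lo = max(0, target.variant_offset - flank)
    hi = min(len(ref) - 1, target.variant_offset + flank)
    if ref_start > lo or ref_end < hi:
        return None

    # identity over alignment columns inside the covered reference span
    in_span = [
        is_match
        for rpos, is_match in columns
        if rpos == -1 or ref_start <= rpos <= ref_end
    ]
    identity = sum(in_span) / len(in_span)
    if identity < min_identity:
        return None
    return PayloadAlignment(ref_to_payload, res["editDistance"], identity, ref_start, ref_end)


def call_read_allele(
    tagged: TaggedRead,
    target: VariantTarget,
    *,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    flank: int = DEFAULT_FLANK,
) -> AlleleObservation:
    """Read out the allele at the variant column of one tagged read."""
    if tagged.cbc is None:
        raise ValueError(f"read {tagged.read_id!r} has no corrected barcode")
    aln = align_payload(tagged.payload_seq, target, min_identity=min_identity, flank=flank)
    if aln is None:
        return AlleleObservation(
            tagged.read_id, tagged.cbc, tagged.umi, tagged.strand, "missing", None, None
        )
    payload_idx = int(aln.ref_to_payload[target.variant_offset])
    if payload_idx < 0:  # variant column deleted in the payload
        return AlleleObservation(
            tagged.read_id, tagged.cbc, tagged.umi, tagged.strand, "missing", None, aln.edits
        )
    base = tagged.payload_seq[payload_idx]
    if base == target.ref_allele:
        allele = "ref"
    elif base == target.alt_allele:
        allele = "alt"
    else:
        allele = "other"
    return AlleleObservation(
        tagged.read_id,
        tagged.cbc,
        tagged.umi,
        tagged.strand,
        allele,
        int(tagged.payload_qual[payload_idx]),
        aln.edits,
    )


def call_alleles(
    tagged_reads: Iterable[TaggedRead],
    target: VariantTarget,
    *,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    flank: int = DEFAULT_FLANK,
) -> pd.DataFrame:
    """Call the variant-column allele for every tagged read.

    Returns a DataFrame with :data:`OBSERVATION_COLUMNS`; unaligned or
    non-covering reads appear with allele ``missing`` so that read counts
    are conserved.
    """
    rows = [
        call_read_allele(t, target, min_identity=min_identity, flank=flank)
        for t in tagged_reads
    ]
    frame = pd.DataFrame(
        [
            (o.read_id, o.cbc, o.umi, o.strand, o.allele, o.base_quality, o.alignment_edits)
            for o in rows
        ],
        columns=OBSERVATION_COLUMNS,
    )
    return frame
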