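"""UMI-consensus allele collapse and Bayesian per-cell genotyping.

Allele observations are first reconciled within each cell: sequencing
errors in the UMI itself are merged directionally (a la UMI-tools), then
each (cell, UMI) group is collapsed to a single consensus allele with a
consensus error probability combining the supporting base qualities.  A
two-state Bayesian model — reference-homozygous versus heterozygous-mutant,
somatic variants being heterozygous — turns a cell's UMI consensuses into a
posterior and a call.  Genotyping runs in one of two modes:

* ``high_specificity`` keeps only UMI consensuses whose exact (cbc, umi)
  also occurs in the matched short-read evidence for the target gene;
* ``high_sensitivity`` uses all consensuses.

Under the reference-homozygous hypothesis each UMI consensus reports the
alt allele only through error, with probability epsilon_umi.  Under the
het-mut hypothesis the alt allele is expressed with fraction beta, so a
consensus reports alt with probability beta*(1-eps) + (1-beta)*eps.  The
posterior is computed in log space; a mut call requires posterior >= tau,
and a ref call additionally requires ``min_umis_ref_call`` UMIs to guard
against allelic dropout mislabeling true het cells as ref.
"""

from __future__ import annotations

import math
import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import edlib
import numpy as np
import pandas as pd

from .alleles import AlleleObservation

MODES = ("high_specificity", "high_sensitivity")

CONSENSUS_COLUMNS = ["cbc", "umi", "allele", "n_reads", "epsilon_umi"]
GENOTYPE_COLUMNS = ["cbc", "n_umi_ref", "n_umi_alt", "posterior_het", "call", "mode"]


@dataclass(frozen=True)
class UmiConsensus:
    cbc: str
    umi: str
    allele: str  # ref | alt
    n_reads: int
    epsilon_umi: float


@dataclass(frozen=True)
class GenotypeModel:
    """Parameters of the two-state per-cell genotype model.

    epsilon_floor : minimum per-UMI consensus error probability; guards
        against overconfident nanopore quality strings.
    beta : expected alt-allele expression fraction in a het cell.
    pi_mut : prior probability that a cell is het-mut (0.5 is
        uninformative; twice the bulk VAF is a sensible informative prior).
    tau : posterior threshold for making a call.
    min_umis_ref_call : minimum UMI support for a ref call (allelic-dropout
        guard; does not apply to mut calls).
    """

    epsilon_floor: float = 0.005
    beta: float = 0.5
    pi_mut: float = 0.5
    tau: float = 0.95
    min_umis_ref_call: int = 2
    mode: str = "high_specificity"

    def __post_init__(self) -> None:
        if not 0 < self.tau < 1:
            raise ValueError("tau must be in (0, 1)")
        if not 0 < self.beta < 1:
            raise ValueError("beta must be in (0, 1)")
        if not 0 <= self.pi_mut <= 1:
            raise ValueError("pi_mut must be in [0, 1]")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")


@dataclass(frozen=True)
class CellGenotype:
    cbc: str
    n_umi_ref: int
    n_umi_alt: int
    posterior_het: float
    call: str  # ref | mut | no-call
    mode: str


def cluster_umis(observations: Sequence[AlleleObservation]) -> list[AlleleObservation]:
    """Directionally merge near-duplicate UMIs within one cell.

    UMI ``u2`` merges into ``u1`` iff their edit distance is <= 1 and
    ``reads(u1) >= 2 * reads(u2) - 1``.  UMIs are visited in deterministic
    order (descending read count, then lexicographic); each UMI merges into
    the first eligible retained UMI.  Returns the observations with merged
    UMI labels rewritten.
    """
    if not observations:
        return []
    cbcs = {o.cbc for o in observations}
    if len(cbcs) != 1:
        raise ValueError(f"cluster_umis expects observations of one cell, got {sorted(cbcs)}")
    counts: dict[str, int] = defaultdict(int)
    for o in observations:
        counts[o.umi] += 1
    order = sorted(counts, key=lambda u: (-counts[u], u))
    canonical: dict[str, str] = {}
    retained: list[str] = []
    for umi in order:
        merged = False
        for parent in retained:
            if counts[parent] >= 2 * counts[umi] - 1 and _umi_distance(parent, umi) <= 1:
                canonical[umi] = parent
                merged = True
                break
        if not merged:
            canonical[umi] = umi
            retained.append(umi)
    out = []
    for o in observations:
        new = canonical[o.umi]
        if new == o.umi:
            out.append(o)
        else:
            out.append(
                AlleleObservation(
                    o.read_id, o.cbc, new, o.strand, o.allele, o.base_quality, o.alignment_edits
                )
            )
    return out


def _umi_distance(u1: str, u2: str) -> int:
    d = edlib.align(u1, u2, mode="NW", task="distance", k=1)["editDistance"]
    return d if d >= 0 else 2


def collapse_umi(
    group: Sequence[AlleleObservation], *, epsilon_floor: float = 0.005
) -> Optional[UmiConsensus]:
    """Collapse the reads of one (cell, UMI) to a consensus allele.

    Missing/other observations carry no ref/alt evidence and are dropped.
    Each allele's weight is the sum of per-read correctness probabilities
    1 - 10^(-q/10); the heavier allele wins, exact ties are discarded.  The
    consensus error probability is the product of the supporting reads'
    error probabilities 10^(-q/10), floored at ``epsilon_floor`` and capped
    at 0.5.
    """
    if not group:
        raise ValueError("collapse_umi: empty group")
    weights = {"ref": 0.0, "alt": 0.0}
    err_prob = {"ref": 1.0, "alt": 1.0}
    n_reads = {"ref": 0, "alt": 0}
    for o in group:
        if o.allele not in weights:
            continue
        p_err = 10.0 ** (-o.base_quality / 10.0)
        weights[o.allele] += 1.0 - p_err
        err_prob[o.allele] *= p_err
        n_reads[o.allele] += 1
    if n_reads["ref"] + n_reads["alt"] == 0:
        return None  # no ref/alt evidence
    if weights["ref"] == weights["alt"]:
        return None  # tie
    allele = "ref" if weights["ref"] > weights["alt"] else "alt"
    epsilon = min(0.5, max(epsilon_floor, err_prob[allele]))
    first = group[0]
    return UmiConsensus(first.cbc, first.umi, allele, n_reads[allele], epsilon)


def build_consensuses(
    observations: Iterable[AlleleObservation], *, epsilon_floor: float = 0.005
) -> list[UmiConsensus]:
    """Cluster UMIs per cell and collapse each (cell, UMI) group."""
    per_cell: dict[str, list[AlleleObservation]] = defaultdict(list)
    for o in observations:
        per_cell[o.cbc].append(o)
    consensuses: list[UmiConsensus] = []
    for cbc in sorted(per_cell):
        merged = cluster_umis(per_cell[cbc])
        groups: dict[str, list[AlleleObservation]] = defaultdict(list)
        for o in merged:
            groups[o.umi].append(o)
        for umi in sorted(groups):
            cons = collapse_umi(groups[umi], epsilon_floor=epsilon_floor)
            if cons is not None:
                consensuses.append(cons)
    return consensuses


def observations_from_frame(frame: pd.DataFrame) -> list[AlleleObservation]:
    """Rebuild allele observations from a table written by the call stage."""
    out = []
    for row in frame.itertuples(index=False):
        bq = None if pd.isna(row.base_quality) else int(row.base_quality)
        ae = None if pd.isna(row.alignment_edits) else int(row.alignment_edits)
        out.append(
            AlleleObservation(row.read_id, row.cbc, row.umi, row.strand, row.allele, bq, ae)
        )
    return out


def filter_high_specificity(
    consensuses: Sequence[UmiConsensus], tags: pd.DataFrame, gene: str
) -> list[UmiConsensus]:
    """Keep consensuses whose exact (cbc, umi) occurs in the short-read tags
    for ``gene``.  Matching is exact (0 edits): the filter exists to
    maximize specificity."""
    gene_tags = tags.loc[tags["gene"] == gene]
    if gene_tags.empty:
        warnings.warn(f"no short-read tags for gene {gene!r}; high-specificity set is empty")
        return []
    allowed = set(zip(gene_tags["cbc"], gene_tags["umi"]))
    return [c for c in consensuses if (c.cbc, c.umi) in allowed]


def genotype_cell(consensuses: Sequence[UmiConsensus], model: GenotypeModel) -> CellGenotype:
    """Posterior over {ref-hom, het-mut} for one cell and the resulting call."""
    if not consensuses:
        raise ValueError("genotype_cell: cell has no UMI consensuses")
    cbcs = {c.cbc for c in consensuses}
    if len(cbcs) != 1:
        raise ValueError(f"genotype_cell expects one cell, got {sorted(cbcs)}")
    log_l_ref = 0.0
    log_l_het = 0.0
    n_ref = n_alt = 0
    for c in consensuses:
        eps = c.epsilon_umi
        p_alt_het = model.beta * (1.0 - eps) + (1.0 - model.beta) * eps
        if c.allele == "alt":
            n_alt += 1
            log_l_ref += math.log(eps)
            log_l_het += math.log(p_alt_het)
        else:
            n_ref += 1
            log_l_ref += math.log1p(-eps)
            log_l_het += math.log1p(-p_alt_het)
    if model.pi_mut == 0.0:
        posterior = 0.0
    elif model.pi_mut == 1.0:
        posterior = 1.0
    else:
        # posterior = pi*L_het / (pi*L_het + (1-pi)*L_ref), in log space
        log_odds = (
            math.log(model.pi_mut) + log_l_het - math.log1p(-model.pi_mut) - log_l_ref
        )
        posterior = 1.0 / (1.0 + math.exp(-log_odds))
    if posterior >= model.tau:
        call = "mut"
    elif (1.0 - posterior) >= model.tau and n_ref >= model.min_umis_ref_call:
        call = "ref"
    else:
        call = "no-call"
    cbc = next(iter(cbcs))
    return CellGenotype(cbc, n_ref, n_alt, posterior, call, model.mode)


def genotype_cells(
    consensuses: Sequence[UmiConsensus],
    model: GenotypeModel,
    *,
    tags: Optional[pd.DataFrame] = None,
    gene: Optional[str] = None,
) -> pd.DataFrame:
    """Genotype every cell with at least one surviving UMI consensus.

    In ``high_specificity`` mode the short-read ``tags`` and target ``gene``
    are required and the UMI-match filter is applied first; cells whose
    evidence is entirely filtered away are absent from the output.
    """
    if model.mode == "high_specificity":
        if tags is None or gene is None:
            raise ValueError("high_specificity mode requires tags and gene")
        consensuses = filter_high_specificity(consensuses, tags, gene)
    per_cell: dict[str, list[UmiConsensus]] = defaultdict(list)
    for c in consensuses:
        per_cell[c.cbc].append(c)
    rows = []
    for cbc in sorted(per_cell):
        g = genotype_cell(per_cell[cbc], model)
        rows.append((g.cbc, g.n_umi_ref, g.n_umi_alt, g.posterior_het, g.call, g.mode))
    return pd.DataFrame(rows, columns=GENOTYPE_COLUMNS)


def consensus_frame(consensuses: Sequence[UmiConsensus]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.cbc, c.umi, c.allele, c.n_reads, c.epsilon_umi) for c in consensuses],
        columns=CONSENSUS_COLUMNS,
    )
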