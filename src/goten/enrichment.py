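"""Cell-type tabulation, mut-fraction normalization, hypergeometric
enrichment and genotyping-efficiency QC.

Genotyped cells are joined with the cell-type annotation and counted per
type.  Because genotyping efficiency differs between cell types, raw mut
counts are normalized to the genotyped cells of each type (mut fraction =
mut / (ref + mut)).  Enrichment of mut cells in a type is assessed with an
upper-tail hypergeometric test — population all genotyped cells of the
tested types, successes the mut cells — with Benjamini-Hochberg correction
across types.  By default only variant-carrying types (those with at least
one mut cell) form the tested family.

A logistic-regression QC models the probability of a cell being genotyped
as a function of its target-gene expression and cell type, since cDNA-based
genotyping favors high expressors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

UNANNOTATED = "unannotated"

TABULATION_COLUMNS = ["cell_type", "n_ref", "n_mut", "n_nocall", "n_genotyped"]
ENRICHMENT_COLUMNS = [
    "cell_type", "n_genotyped", "k_mut", "mut_fraction", "p_raw", "p_adj",
]


def tabulate_genotypes(genotypes: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Count ref / mut / no-call cells per annotated cell type.

    ``genotypes`` needs columns ``cbc`` and ``call``; ``annotation`` maps
    ``cbc`` to ``cell_type``.  Cells absent from the annotation are counted
    under ``unannotated``.  A duplicated barcode in ``genotypes`` is a hard
    error.  ``n_genotyped`` is ref + mut (no-calls are not genotyped).
    """
    if genotypes["cbc"].duplicated().any():
        dup = genotypes.loc[genotypes["cbc"].duplicated(), "cbc"].iloc[0]
        raise ValueError(f"barcode {dup!r} appears more than once in the genotype table")
    if genotypes.empty:
        return pd.DataFrame(columns=TABULATION_COLUMNS).astype(
            {c: np.int64 for c in TABULATION_COLUMNS[1:]}
        )
    merged = genotypes.merge(annotation, on="cbc", how="left")
    merged["cell_type"] = merged["cell_type"].fillna(UNANNOTATED)
    counts = (
        merged.pivot_table(index="cell_type", columns="call", values="cbc",
                           aggfunc="count", fill_value=0, observed=True)
        .reindex(columns=["ref", "mut", "no-call"], fill_value=0)
        .rename(columns={"ref": "n_ref", "mut": "n_mut", "no-call": "n_nocall"})
        .reset_index()
    )
    counts["n_genotyped"] = counts["n_ref"] + counts["n_mut"]
    counts = counts.sort_values("cell_type", ignore_index=True)
    counts.columns.name = None
    return counts[TABULATION_COLUMNS]


def case_summary(genotypes: pd.DataFrame) -> dict:
    """Pooled genotyping summary: genotyped (ref+mut), ref, mut, mut %."""
    n_ref = int((genotypes["call"] == "ref").sum())
    n_mut = int((genotypes["call"] == "mut").sum())
    return {
        "n_cells": int(len(genotypes)),
        "n_genotyped": n_ref + n_mut,
        "n_ref": n_ref,
        "n_mut": n_mut,
        "mut_fraction_pct": mut_fraction(n_mut, n_ref) if n_ref + n_mut else float("nan"),
    }


def mut_fraction(k_mut: int, n_ref: int) -> float:
    """Percentage of mut cells among genotyped cells, to one decimal.

    100 * k_mut / (k_mut + n_ref); a zero denominator is undefined (NaN).
    """
    if k_mut < 0 or n_ref < 0:
        raise ValueError("counts must be non-negative")
    denom = k_mut + n_ref
    if denom == 0:
        return float("nan")
    return round(100.0 * k_mut / denom, 1)


def enrichment_test(
    counts: pd.DataFrame, *, restrict_to_variant_carrying: bool = True
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of mut cells per cell type.

    ``counts`` needs columns ``cell_type``, ``n_genotyped`` and ``k_mut``
    (``tabulate_genotypes`` output works, with ``n_mut`` accepted as an
    alias).  With ``restrict_to_variant_carrying`` (default) only types with
    at least one mut cell enter the tested family, and the population
    N / successes K are formed from those types alone.  For type t,
    ``p_raw = P(X >= k_t)`` with X hypergeometric(N, K, n_t) — the observed
    k is included, the standard tail convention — and ``p_adj`` is the
    Benjamini-Hochberg step-up over the tested types.
    """
    table = counts.rename(columns={"n_mut": "k_mut"}).copy()
    required = {"cell_type", "n_genotyped", "k_mut"}
    if not required <= set(table.columns):
        raise ValueError(f"enrichment_test needs columns {sorted(required)}")
    if restrict_to_variant_carrying:
        table = table.loc[table["k_mut"] > 0]
    table = table.loc[table["n_genotyped"] > 0].reset_index(drop=True)
    if table.empty:
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS)
    if len(table) == 1:
        warnings.warn("only one tested cell type: enrichment p-value is 1 by construction")
    N = int(table["n_genotyped"].sum())
    K = int(table["k_mut"].sum())
    p_raw = hypergeom.sf(table["k_mut"].to_numpy() - 1, N, K, table["n_genotyped"].to_numpy())
    p_raw = np.clip(p_raw, 0.0, 1.0)
    p_adj = multipletests(p_raw, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "cell_type": table["cell_type"],
            "n_genotyped": table["n_genotyped"].astype(np.int64),
            "k_mut": table["k_mut"].astype(np.int64),
            "mut_fraction": [
                mut_fraction(int(k), int(n - k))
                for k, n in zip(table["k_mut"], table["n_genotyped"])
            ],
            "p_raw": p_raw,
            "p_adj": p_adj,
        }
    )
    return out.sort_values(["p_adj", "p_raw", "cell_type"], ignore_index=True)


@dataclass
class EfficiencyQcResult:
    """Logistic-regression QC of genotyping probability.

    ``coefficients`` holds one row per model term (intercept, log1p
    expression slope, cell-type indicator effects) with estimate, standard
    error, Wald z and p-value.  ``stable`` is False when the fit shows signs
    of (quasi-)separation and the coefficients should not be interpreted.
    """

    coefficients: pd.DataFrame
    stable: bool


def genotyping_efficiency_qc(cells: pd.DataFrame) -> EfficiencyQcResult:
    """Regress genotyping success on expression and cell type.

    ``cells`` needs columns ``genotyped`` (bool/0-1), ``log1p_expression``
    and ``cell_type``; at least 2 cell types and 50 cells are required.
    """
    required = {"genotyped", "log1p_expression", "cell_type"}
    if not required <= set(cells.columns):
        raise ValueError(f"genotyping_efficiency_qc needs columns {sorted(required)}")
    if len(cells) < 50:
        raise ValueError("need at least 50 cells for the efficiency QC")
    if cells["cell_type"].nunique() < 2:
        raise ValueError("need at least 2 cell types for the efficiency QC")
    types = pd.get_dummies(cells["cell_type"], prefix="cell_type", drop_first=True, dtype=float)
    X = sm.add_constant(
        pd.concat([cells[["log1p_expression"]].astype(float), types], axis=1)
    )
    y = cells["genotyped"].astype(float)
    stable = True
    with warnings.catch_warnings():
        warnings.simplefilter("error")
        try:
            fit = sm.Logit(y, X).fit(disp=0)
        except Exception:  # separation or non-convergence: refit leniently
            stable = False
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    if not np.all(np.isfinite(fit.bse)) or np.any(fit.bse > 50):
        stable = False
    coefficients = pd.DataFrame(
        {
            "term": X.columns,
            "estimate": fit.params.to_numpy(),
            "std_err": fit.bse.to_numpy(),
            "z": fit.tvalues.to_numpy(),
            "p_value": fit.pvalues.to_numpy(),
        }
    )
    return EfficiencyQcResult(coefficients, stable)
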