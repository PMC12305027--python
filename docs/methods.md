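# Methods

`goten` genotypes known somatic single-nucleotide variants in single nuclei
by combining two views of the same 10X cDNA pool: targeted long-read
amplicons that span the variant locus together with the cell barcode (CBC)
and unique molecular identifier (UMI), and the matched short-read snRNA-seq
library that supplies the barcode whitelist, the per-gene (cbc, umi)
evidence and the cell-type annotation. This note describes the model and
procedure each stage implements, the parameters that matter, and the
choices made where the design was genuinely open.

## Read tagging

A long amplicon read is expected to contain, in one orientation,

```
[constant anchor][16-nt CBC][12-nt UMI][amplicon payload]
```

The anchor is the constant sequence immediately 5' of the barcode; the
default is the 10X partial read-1 primer `CTACACGACGCTCTTCCGATCT` (22 nt).
It is located by bounded semi-global (infix) edit distance on the read and
its reverse complement; a hit is accepted when its edit distance is at most
`ceil(max_anchor_mismatch_frac × anchor length)` (default fraction 0.15,
i.e. 4 edits for the default anchor). When both strands produce hits at the
same distance the '+' orientation wins; this is the documented contract of
the anchor search, and in practice such ties occur only for degenerate
anchor-like repeats.

Edit (Levenshtein) distance is used throughout rather than Hamming because
nanopore errors are indel-dominated. Barcode correction finds the unique
whitelist entry within `max_cbc_edits` (default 1) of the raw 16-mer; exact
matches always win, and ties at the minimal distance are rejected as
ambiguous rather than guessed. Because the extracted raw barcode always has
the whitelist length, Levenshtein distance 1 coincides with Hamming
distance 1, so the default correction is an exact substitution-neighborhood
dictionary lookup; larger radii fall back to a bounded scan. Base
qualities are deliberately ignored during correction: nanopore quality
strings are not calibrated well enough at the single-barcode scale to beat
a pure distance rule.

Every rejected read is counted under one of four reasons (`too-short`,
`no-anchor`, `cbc-unmatched`, `cbc-ambiguous`) so that reads in = reads
tagged + reads rejected at all times.

## Allele readout

The payload downstream of the UMI is aligned semi-globally to the amplicon
reference (payload end overhangs free). The alignment is accepted when its
identity over the reference span actually covered by payload bases is at
least 0.75 and that span covers the variant position ±15 nt; both
thresholds are configuration, chosen to tolerate raw nanopore error rates
while rejecting off-target amplicons, whose identity to the reference sits
near 25%. The base aligned to the variant column and its FASTQ quality
become the read's allele observation: `ref`, `alt`, a third base (`other`),
or `missing` when the column is deleted or the read does not align. `other`
observations are retained in outputs as an error-rate diagnostic but never
count as ref or alt evidence. Variant positions are 0-based within the
amplicon; 1-based VCF-style positions in user configuration are converted
once at load time.

## UMI consensus

Within each cell, UMI labels one edit apart are merged directionally
(descending read count, then lexicographic): `u2` merges into `u1` iff
`reads(u1) ≥ 2·reads(u2) − 1`, the standard directional-network rule for
separating UMI sequencing errors from distinct molecules. Each (cell, UMI)
group is then collapsed: per-allele weight is the sum of per-read
correctness probabilities `1 − 10^(−q/10)`, the heavier allele becomes the
consensus, and exact ties are discarded. The consensus error probability
is the product of the supporting reads' error probabilities — the
independent-error combination — floored at `epsilon_floor` (default 0.005)
because context-dependent nanopore error hotspots make extreme products
untrustworthy, and capped at 0.5.

## Per-cell Bayesian genotype

Somatic variants in this setting are heterozygous, so the genotype space is
restricted to two states: reference-homozygous and heterozygous-mutant.
For a cell with UMI consensuses having error probabilities ε_i:

- under ref-hom, consensus i reports alt with probability ε_i;
- under het-mut, it reports alt with probability β(1−ε_i) + (1−β)ε_i,
  where β is the expected alt-allele expression fraction (default 0.5,
  exposed because allelic imbalance and transcriptional bursting can skew
  transcript ratios).

With prior π = P(het-mut) (default 0.5, uninformative; twice the bulk VAF
is a sensible informative alternative), the posterior follows from Bayes'
rule, evaluated in log space. A `mut` call requires posterior ≥ τ (default
0.95); a `ref` call requires the complementary posterior ≥ τ **and** at
least `min_umis_ref_call` (default 2) UMIs, because a het cell expressing
only its reference allele is indistinguishable from ref-hom at low depth
(allelic dropout). Everything else is `no-call`. With the defaults, a pure
ref cell needs five concordant UMIs before the posterior clears τ, whereas
a single alt UMI is close to sufficient for a mut call — an intentional
asymmetry: a consensus-level alt observation is far less likely under
ref-hom (probability ε) than a ref observation is under het-mut
(probability ≈ 1−β).

Two modes control which consensuses are eligible. `high_specificity`
keeps only consensuses whose exact (cbc, umi) also occurs in the
short-read evidence for the target gene — exact matching, zero edits,
because the filter exists to maximize specificity. `high_sensitivity`
uses all consensuses. The high-specificity cell set is therefore always a
subset of the high-sensitivity set, a property the test suite checks on
simulated runs.

## Enrichment statistics

Genotyping efficiency differs between cell types, so raw mut counts are
normalized per type: mut fraction = mut / (ref + mut), reported as a
percentage to one decimal. Enrichment of mut cells in a type is assessed
with an upper-tail hypergeometric test — population N = all genotyped
cells of the tested types, successes K = their mut cells, draws n_t = the
type's genotyped cells, P(X ≥ k_t) including the observed k — with
Benjamini-Hochberg correction across types. By default the tested family
is restricted to variant-carrying types (k_t > 0), comparing each such
type against the other variant-carrying types; a flag widens the family to
all genotyped types. Cells missing from the annotation are tabulated under
an `unannotated` pseudo-type but never enter the tested family. A single
tested type yields p = 1 by construction and emits a warning.

The genotyping-efficiency QC fits a maximum-likelihood logistic regression
of per-cell genotyping success on log1p target-gene expression plus
cell-type indicators, since cDNA-based genotyping necessarily favors high
expressors. Perfect or quasi-separation is detected (non-finite or huge
standard errors, failed strict fit) and flagged as unstable rather than
silently reported.

## Simulator

The simulator generates all five pipeline inputs with known truth. Each of
`n_cells` cells draws a type from `cell_type_probs` and a genotype
(het-mut with probability `mosaic_fraction`; bulk VAF ≈ mosaic fraction /
2 for a heterozygous variant). Per-cell on-target transcript counts are
Poisson with a per-type mean (default 6); each transcript receives a
unique UMI and an allele (alt with probability `beta_true` in het cells),
and is amplified into a geometric (min 1, mean `reads_per_umi`, default 3)
number of noisy reads constructed as anchor + CBC + UMI + amplicon.
Substitution (default 0.02/base) and indel (default 0.01/base) errors are
position-independent; per-base qualities are drawn within ±2 of the Phred
equivalent of the substitution rate so that consensus arithmetic operates
on calibrated inputs. Half the reads are emitted reverse-complemented.
The whitelist is the true barcode set plus 10× decoys to exercise
correction; the tag table holds every true (cbc, umi, gene) triple,
optionally thinned by a capture probability. Simulated amplicons default
to 500 nt with the variant at offset 250. A fixed seed makes every output
byte-identical.

What the simulator does **not** emulate: homopolymer-aware or
context-dependent error profiles, chimeric reads, ambient RNA, doublets,
transcript-isoform effects on amplicon capture, and cell-type-correlated
genotype assignment. Passing tests therefore demonstrate correctness of
the algorithms under idealized position-independent noise and honest
recovery of mosaic fractions under that model — not robustness to every
artifact of real nanopore amplicon libraries.

## Numerical and procedural choices

- Posteriors are computed in log space; the oracle-equivalence test checks
  agreement with direct probability-space evaluation to 1e-10 over all
  evidence configurations up to 6 UMIs.
- All written tables are sorted on their key columns so repeated runs are
  bit-identical; NaN serializes as `NA`.
- Test and validation cohorts use 300–500-nt amplicons and 30–500 cells
  (up to ~14,000 reads); these sizes give binomial 99% confidence
  intervals a few percentage points wide for the recovery checks while
  keeping the whole suite fast on one CPU.
- The null-calibration check uses 8 types × 250 genotyped cells so the
  discrete hypergeometric tail is fine-grained enough for the empirical
  type-I error (~0.045) to sit near the nominal 0.05.

## Known limitations

- Only single-nucleotide variants are supported; indel or multi-nucleotide
  variants and phasing are out of scope.
- One variant is genotyped per run; joint genotyping across loci and
  copy-number-aware models are not implemented.
- The per-UMI error model treats consensuses as independent; PCR jackpot
  errors that propagate one early error into many UMIs violate this and
  are mitigated only by `epsilon_floor`.
- The published per-cell-type count table needed to reproduce the reported
  cell-type enrichment p-value ships only as controlled supplementary
  data; the enrichment machinery is instead validated by exhaustive
  enumeration and permutation-invariance checks.
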