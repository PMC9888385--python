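# Methods

This note documents the statistical models behind each `angiolnc`
module, the parameters that matter, the design choices made where the
procedure was genuinely open, and what the synthetic benchmarks do and do
not demonstrate.

## Divergent-regulation screen

Inputs are three per-gene contrast tables (columns `gene_id, log2fc,
pvalue, padj`): hypoxia vs. normoxia (Hx), high glucose vs. osmolarity
control (HG), and TNF-α vs. untreated control. "FC" is interpreted
throughout as the log₂ fold change, the scale standard DE tools report;
on that scale the divergence score

D = |FC_Hx − FC_HG| + |FC_Hx − FC_TNF|

treats up- and downregulation symmetrically (D is invariant under joint
negation of all three inputs) and is scale-equivariant (multiplying all
log-fold changes by c > 0 multiplies D by c).

Candidate filter: a gene must be significant (`padj < α`, default
α = 0.05) in the Hx contrast **and** in at least one diabetic contrast,
and every *significant* diabetic response must have sign opposite to the
Hx response. A non-significant diabetic contrast neither qualifies nor
vetoes a gene — its point estimate is still used in D, since the score is
defined on all three fold changes unconditionally. Genes missing from any
table are dropped from ranking with a logged warning rather than imputed.
Ties in D are broken lexicographically by gene id so output is
deterministic. An independent loop-based reimplementation of
filter + score + rank is kept in the test suite as an oracle.

## Single-cell QC and annotation

Cells live in an `AnnData` with raw integer counts; `n_genes_expressed`
and `mito_fraction` are always derived from the counts (genes named with
an `mt-` prefix count as mitochondrial). QC removes cells *strictly over*
3,000 expressed genes (multiplet proxy) or *strictly over* 25%
mitochondrial reads; boundary cells are kept, and the filter is
idempotent. Normalization is `ln(1 + count · scale / cell_total)` with
`scale` = 10,000, which is invariant to sequencing depth per cell.

Annotation proceeds per cell type in the marker panel:

1. **Meta-marker** — the arithmetic mean of the panel genes' normalized
   expression per cell, giving one 1-D value per cell.
2. **Mixture binarization** — a two-component univariate Gaussian
   mixture is fitted to the meta-marker by EM. Initialisation splits the
   sorted values at the median (deterministic; optional seeded random
   restarts exist but are off by default). A variance floor of
   10⁻⁶ × var(data) prevents collapse onto point masses. The
   log-likelihood is asserted nondecreasing at every iteration — a
   property of exact EM, so any violation indicates an implementation
   fault rather than a data problem. Cells whose posterior under the
   larger-mean component exceeds 0.5 are "marker-high" (a tie goes to
   low); flags are invariant to component relabeling. The fit requires at
   least 4 distinct values; constant vectors are rejected.
3. **Fisher enrichment** — for each (cluster, cell type), the 2×2 table
   of cluster membership × marker-high status over all retained cells is
   tested one-sided for enrichment (upper hypergeometric tail,
   P(X ≥ a)). Each cluster receives the type with the smallest p-value;
   exact ties resolve to the type declared first in the panel.

The table construction (cluster × marker-high over all cells, one-sided)
is a design choice: it directly operationalises "is this cluster enriched
for marker-high cells". The mixture is fitted on log-normalized values.
Cluster labels are pluggable input — any clustering can be supplied; a
PCA + k-means utility (`cluster_cells_basic`, 15 PCs by default) exists
only so that synthetic end-to-end runs need no external tool.

The default marker panel is the vascular one used throughout the tests:
Cdh5/Pecam1 (ECs), Acta2 (VSMC), Itgam/Adgre1/Fcgr1 (macrophages),
S100a4 (fibroblasts).

## Differential expression stand-in and set integration

`de_test_simple` is intentionally modest: size factors by median of
ratios (reference = per-gene geometric mean over samples with full
support), log₂(normalized + 1) transform, pooled two-sample *t* per gene,
BH adjustment. Pooled rather than Welch *t*: with the balanced 3–4
replicate designs this targets, the pooled test holds its nominal level
(measured type-I ≈ 0.049 at α = 0.05 on exactly normal nulls), whereas
the Welch approximation is markedly conservative (≈ 0.041) below five
replicates per group. The engine is a stand-in for full count-model DE
frameworks; the downstream set logic, not the DE engine, is what this
package contributes, and any DE table with `gene_id/log2fc/pvalue/padj/
direction` columns can be substituted.

Set logic: *rescued genes* = (down in KO vs. WT at padj < α) ∩ (up in
OE vs. KO at padj < α); *regulome* = (down on knockdown) ∩ (bound);
*putative direct targets* = in-vitro ∩ in-vivo ∩ bound. Reports carry
provenance (which inputs produced them). Cross-species id translation is
a caller-supplied two-column table (`map_ids`); no remote lookups.

Single-cell DEG counting (`sc_deg_count`): per cell type, Wilcoxon
rank-sum per gene between two conditions on log-normalized expression, BH
within the type, DEG iff padj < α and |difference of mean log
expression| > 0.25. The fold-change cutoff is on the natural-log scale of
the normalized values (the same scale the normalization produces); the
base is a documented choice and the cutoff is a parameter.

## Peak annotation

Coordinates are 0-based half-open (BED) everywhere; the promoter window
is TSS ± 3 kb, closed on both ends in base space. Strand affects only
where the TSS sits (span start on `+`, span end − 1 on `−`); overlap
tests are strand-agnostic and require at least one shared base.
Categories are assigned with priority promoter > exon > intron >
intergenic; among genes tied at the winning priority, the nearest TSS
wins, then lexicographic gene id. Enlarging the window can only promote
peaks into the promoter category, never out of it. Lookup uses interval
trees; a naive O(n·m) scan in the tests serves as the oracle.
`bound_genes` applies the 1-base gene-body overlap rule; adjacency in
half-open coordinates (peak end == gene start) is not an overlap.

## Ligand-receptor permutation test

Score(pair, sender → receiver) = (mean ligand expression in sender
cells + mean receptor expression in receiver cells) / 2, on normalized
expression; autocrine pairs use the same formula. The null shuffles the
cell-type labels globally (preserving type sizes) and recomputes the
score; p = (1 + #{null ≥ observed}) / (n_perm + 1), one-sided for
enrichment, so p ∈ [1/(n_perm+1), 1] and is never zero. This is a
single-gene simplification of permutation-based cell-communication tools:
multi-subunit complexes and expressed-fraction thresholds are deliberately
out of scope, which makes the statistic fully specified and testable.
Significant results (p < α) form a directed multigraph (edges labeled by
pair); network comparison reports gained/lost labeled edges between
conditions.

## Synthetic data: what it emulates and what it does not

All generators draw from independent, named substreams of one global
seed, so identical configurations reproduce byte-identical outputs and
adding one generator never perturbs another.

* **Contrast tables** — planted genes get a ±`effect_size` (default 2)
  log₂FC in Hx and the mirrored sign in both diabetic contrasts;
  background genes carry independent N(0, `noise_sd`) noise
  (default SD 0.25). P-values are two-sided z-tests with `noise_sd`
  treated as the known standard error, BH-adjusted. This emulates the
  *statistical shape* of a three-way DE comparison, not count-level
  variability.
* **Cell datasets** — negative-binomial counts (var = μ + φμ²,
  single-cell dispersion φ = 0.5) over a ~4,000-gene universe containing
  10 `mt-` genes and the marker panel; marker means are multiplied by
  exp(`marker_elevation`) in the cell's own type (default elevation 2.0,
  200 cells per type). Mitochondrial fractions are Beta(2, 38) for normal
  cells (clipped below the 25% cutoff) and Uniform(0.30, 0.60) for
  planted outliers (default rate 0.05), so the QC cutoff identifies the
  planted set exactly; mitochondrial counts are allocated multinomially
  at the drawn fraction. Multiplet-like cells (default rate 0.02) get a
  6-fold library boost, which pushes them past 3,000 expressed genes by
  construction. Cluster labels default to the true type because
  clustering is treated as input. Not emulated: batch effects, ambient
  RNA, true doublet expression profiles, gene-gene correlation.
* **Genome fixture** — non-overlapping three-exon genes of 12 kb
  alternating strand with 14 kb gaps, so each peak category has
  unambiguous room; peaks (200 bp) are planted per category at requested
  proportions using the same priority rules the classifier applies, which
  is why exact recovery is the correct expectation. Overlapping-gene
  behaviour is exercised by hand-written fixtures, not the generator.
* **Rescue design** — three groups (WT+GFP, KO+GFP, KO+OE) of
  negative-binomial counts (bulk dispersion φ = 0.01, "low"; base means
  lognormal around 200), 4 replicates each; planted genes (default 20 of
  500) are reduced 2^`effect_size`-fold in KO and fully restored in OE.

Because the planted effects follow the same rules the detectors test
for, the recovery benchmarks demonstrate *internal correctness and
statistical calibration* of the pipeline — they do not establish
performance on real sequencing data, whose noise structure is richer.

## Benchmark sizes and numerical choices

The packaged benchmarks use: 50 seeded screen runs (1,000 genes, 10
planted), 100 mixture fits (n = 1,000, 5σ separation; worst-case mean
error observed ≈ 0.15), 50 annotation runs (800 cells) plus an
elevation sweep {0, 0.5, 1, 2} checking monotone accuracy, 20 rescue
runs, 1,000 planted peaks, 1,000 null permutation tests at n_perm = 199,
and a 2,000-gene DE null. These sizes give tight Monte-Carlo bands while
keeping a full run around half a minute. EM convergence is declared at a
log-likelihood change < 10⁻⁶ (cap 500 iterations). The power benchmark
plants a cohort of ten 2-fold genes in a 100-gene universe because a BH
threshold cannot be cleared by a single moderate effect among a large
pure null at 4 replicates — detection there is a property of the cohort
design, not of the test alone.

## Known limitations

* The DE stand-in ignores count-model shrinkage and dispersion
  estimation; it is calibrated for the balanced small-n synthetic designs
  it ships with.
* The ligand-receptor statistic handles single-gene ligands/receptors
  only and one-sided enrichment.
* The mixture binarization assumes the meta-marker distribution is
  reasonably two-component; heavily skewed unimodal distributions will
  still be split, and downstream Fisher p-values — not the split itself —
  carry the inferential weight.
* Cell counts, DEG counts, and peak-category percentages obtained from
  real deposited datasets depend on upstream alignment, clustering and
  annotation tools outside this package's scope.
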