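# Methods

This note documents the models, parameter choices and numerical decisions
behind `exocomm`, and what the synthetic test bed does and does not show
about real data.

## The communication model

The pipeline treats cell–cell communication as set logic over curated
knowledge, not as expression-weighted scoring. An exosomal protein is a
*ligand* if it appears in the curated ligand set after ortholog mapping; a
tissue gene is a *cell-type receptor* if it is a statistically strong
marker (adjusted p ≤ 0.01) of that cell type and appears in the curated
receptor set. Communication is then asserted for every curated directed
ligand→receptor pair whose two endpoints *participate* in shared biology —
operationalized as membership in GO-BP terms that are over-represented in
both the ligand list and the receptor list at adjusted p < 0.05. No
significance is attached to individual edges; the network is as good as
the curated reference and the enrichment cutoffs. This deliberately
reproduces the set-logical construction rather than CellPhoneDB/CellChat
style permutation scoring, which is an explicit non-goal.

Edge identity for all network comparisons is the (ligand, receptor) pair;
receptor cell types are merged metadata. An edge's supporting terms are
the shared terms containing its ligand on the ligand side — participation
is defined per molecule, not per pair, so requiring the receptor in the
same term would be a stricter criterion than the construction implies.
The consensus network is the full k-way intersection of the named
condition networks.

## Statistical components

* **Hypergeometric upper tail.** P(X ≥ k) for X ~ Hypergeom(N, K, n) is
  summed in log space (log-gamma binomial coefficients, running
  log-add-exp), so deeply significant terms do not underflow; agreement
  with exact integer summation is ~1e-13 relative over the exhaustive
  N ≤ 60 grid. Only terms with overlap ≥ 1 and restricted size in
  [3, 2000] are tested; BH runs over the tested terms only (both choices
  recorded in the table metadata, both configurable).
* **Universe convention.** The enrichment universe defaults to the
  annotation's gene union intersected with the relevant measured
  namespace: mapped proteome symbols on the ligand side, detected
  (post-QC) genes on the receptor side. This is the dominant ORA
  convention; it is explicit and configurable rather than inferred.
* **BH-FDR.** Step-up with a final elementwise max against the raw
  p-values: mathematically q ≥ p always holds, but one floating-point
  rounding can otherwise dip 1 ulp below the raw value and violate the
  table invariant.
* **Wilcoxon rank-sum.** The production path is the normal approximation
  with tie correction and a 0.5 continuity correction, two-sided —
  appropriate at typical cluster sizes. An exact path enumerates all
  C(n1+n2, n1) assignments and reports min(1, 2·min(P(W≤w), P(W≥w)));
  it is used (and cross-checked against an independent Fraction-counted
  oracle) for group sizes up to 8.
* **QC semantics.** Retain iff min_genes ≤ detected ≤ max_genes; the mito
  rule removes strictly above the threshold (the boundary value is
  retained — "over X%" reads as strict). Cell metrics are computed on the
  raw matrix before gene filtering and never recomputed, which makes the
  filter order-deterministic. Idempotence on its own output holds
  whenever removing rare genes does not push a retained cell below
  min_genes; the generator's margins guarantee this on the synthetic bed
  and the property is asserted there.
* **Clustering.** PCA uses a deterministic full SVD on the z-scored
  (clipped at ±10) HVG submatrix; the k = 30 nearest-neighbor graph is
  re-weighted by Jaccard shared-neighbor overlap, pruned below 1/15, and
  partitioned by Leiden (RB configuration quality) at resolution 0.5 with
  an explicit seed. The exact community-detection flavor is an
  implementation contract — verified by planted-partition recovery and
  determinism, not by matching any particular cluster count. Labels are
  renumbered by descending cluster size.
* **Marker listing vs receptor selection.** `return_thresh = 0.05`
  applies to the raw p when listing markers (the convention of the
  reference single-cell toolchain); the adjusted p ≤ 0.01 cutoff is
  applied downstream when selecting receptors. BH adjustment is per cell
  type over the tests actually performed.
* **Batch handling.** Tissues are processed independently end to end; the
  cross-match consumes per-tissue outputs, so no integration/batch
  correction step exists and provenance is carried by the per-tissue
  source labels on edges.

## The synthetic test bed

The generator's defaults are the package's study conditions: 2 tissues ×
3 cell types (EC/FB/MAC) with distinct compositions (480/400/320 vs
320/480/400 cells), 2,000 genes plus 13 `mt-` genes, 30 planted ligands,
24 planted receptors (EC-weighted 11/8/5), 40 planted pairs, 6 shared GO
terms among 40, marker fold 4, seed 7.

Counts are negative binomial with mean 0.5 and dispersion 2 (variance
μ + μ²/r); mitochondrial genes run at 8× the baseline mean, giving ~5 %
mito fractions in healthy cells, far from both thresholds. Planted
markers (including every planted receptor) are up-regulated by
`marker_fold` in their host type only. QC violators are constructed
explicitly — 100-gene cells, (max_genes + 50)-gene cells when the gene
universe allows, and cells with mito fractions at twice the tissue
threshold — rather than sampled from the NB tail, so filter tests are
exact; two "rare" genes appear in exactly 2 cells to exercise the
min-cells-per-gene rule.

Species namespaces are simulated by case (upper-case "human" proteome,
capitalized "mouse" tissue symbols) with an explicit ortholog table; a
10 % alias fraction is deliberately omitted from the table and must be
recovered by case-insensitive fallback, so the mapping path is exercised
end to end.

Shared GO terms are built to satisfy the generator's contract that both
sides enrich and that full recovery is attainable: each shared term hosts
one cell type, contains ≥ 3 of that type's receptors (topped up to 8
receptors borrowed across types) and 10 planted ligands, and together the
shared terms cover every planted ligand and receptor. Non-shared terms
draw uniformly from the annotation universe *excluding* planted ligands
and receptors — this makes the planted terms exactly the cross-matchable
ones, so recovery tests can assert set equality instead of a fuzzy
overlap. The exclusion is the one place the generator departs from fully
uniform fills, and it is a deliberate design choice.

What passing tests show: every stage behaves exactly as specified under
NB noise with planted, well-separated effects, and the whole chain
composes into exact network recovery. What they do not show: robustness
to gene–gene correlation, batch effects, doublets, ambient RNA, shallow
or highly variable sequencing depth, annotation incompleteness, or
imperfect ortholog curation — none of which the generator models.
Proteome entries are presence/absence only (no intensities), matching how
the pipeline consumes them.

On this bed, recall of the planted pairs degrades monotonically as
`marker_fold` drops toward 1: at fold 4 and 3 recovery is exact; below
that, the SNN/Leiden stage no longer separates the populations at these
gene counts and cell numbers, marker detection collapses, and recall
falls to zero. The cliff is a property of the small synthetic universe
(all ~2,000 genes enter the PCA because the 2,500-HVG default clamps to
the gene count), not of the marker test, whose prefilters
(log-FC ≥ 0.25) would admit fold-1.5 markers if clustering succeeded.

## Problem sizes and runtime choices

The default bundle (2 × 1,200 cells × 2,013 genes) runs the full pipeline
in a few seconds per tissue on one CPU; the test suite and the acceptance
script stay within a couple of minutes by using this scale plus a smaller
400-gene bundle (with proportionally stronger planted effects, fold 8)
for per-stage unit tests, and a dedicated 4,500-gene bundle for the
high-gene QC rule, which is impossible to violate when the gene universe
is smaller than max_genes. These sizes are package choices made once; all
randomness in generation and clustering flows from explicit seeds, and a
fixed seed regenerates every artifact byte-identically.

## Known limitations

* The L-R reference is a required input; the package ships only synthetic
  references, and results inherit any curation bias of the supplied one.
* GO terms are flat sets: no DAG propagation, no redundancy collapsing.
  KEGG-style collections run through the same engine as plain gene sets.
* The receptor–pathway correlation table (Pearson r between a receptor's
  normalized expression and the mean expression of a term's other member
  genes, within one cell type) is exploratory; its exact construction is
  a documented package choice and its outputs are labeled as such.
* Receptors may mark several cell types; network restriction to one type
  keeps any edge whose receptor is hosted there, which is permissive —
  the alternative (receptors exclusive to the type) can be obtained by
  pre-filtering the receptor map.
* A tissue whose clustering yields fewer than two annotated types
  produces an empty marker table (logged), hence an empty network, rather
  than an error — the multi-condition intersection treats it as an
  all-absent condition.
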